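El tren de la mañana salió de la estación con unos minutos de retraso, y
los pasajeros se acomodaron en sus asientos con periódicos y tazas de café.
Por la ventana, los campos todavía estaban cubiertos por una fina capa de
niebla, y la primera luz del sol tocaba los tejados de las pequeñas casas a
lo largo de la vía. Una mujer joven abrió su libro y empezó a leer,
mientras un hombre mayor, al otro lado del pasillo, miraba el campo que
pasaba y pensaba en el largo día que le esperaba. El tiempo había sido
inusualmente cálido para esta época del año, y todo el mundo hablaba de la
próxima cosecha y se preguntaba si la lluvia llegaría a tiempo. En el
pueblo mismo, las tiendas abrían una tras otra. El panadero sacaba panes
frescos, el tendero colocaba cajas de manzanas y peras sobre las mesas
delante de su tienda, y los niños iban a la escuela en pequeños grupos,
riendo y llamándose unos a otros a través de la calle. Era un día
corriente, y sin embargo había algo agradable en el ritmo tranquilo de todo
aquello, la sensación de que las cosas sucedían en su orden debido y a su
debido tiempo. Más tarde, por la tarde, cuando el calor del día hubiera
pasado, la gente se reuniría en la plaza cerca de la vieja fuente para
hablar de las noticias, de sus familias y de las pequeñas cosas que forman
una vida en un lugar donde todos conocen a todos por su nombre.
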