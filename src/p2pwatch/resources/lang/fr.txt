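Le train du matin a quitté la gare avec quelques minutes de retard, et les
voyageurs se sont installés à leurs places avec des journaux et des tasses
de café. Par la fenêtre, les champs étaient encore couverts d'une fine
couche de brume, et la première lumière du soleil touchait les toits des
petites maisons le long de la voie. Une jeune femme a ouvert son livre et a
commencé à lire, tandis qu'un homme plus âgé, de l'autre côté du couloir,
regardait la campagne qui défilait et pensait à la longue journée qui
l'attendait. Le temps avait été exceptionnellement doux pour cette période
de l'année, et tout le monde parlait de la récolte à venir et se demandait
si la pluie arriverait à temps. Dans la ville même, les magasins ouvraient
l'un après l'autre. Le boulanger sortait des pains frais, l'épicier
disposait des caisses de pommes et de poires sur les tables devant sa
boutique, et les enfants allaient à l'école en petits groupes, riant et
s'appelant d'un côté à l'autre de la rue. C'était une journée ordinaire, et
pourtant il y avait quelque chose d'agréable dans le rythme tranquille de
tout cela, le sentiment que les choses se passaient dans le bon ordre et au
bon moment. Plus tard dans l'après-midi, quand la chaleur du jour serait
passée, les gens se réuniraient sur la place près de la vieille fontaine
pour parler des nouvelles, de leurs familles, et des petites choses qui
font une vie dans un endroit où chacun connaît tout le monde par son nom.
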