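The morning train left the station a few minutes late, and the passengers
settled into their seats with newspapers and cups of coffee. Outside the
window, the fields were still covered with a thin layer of mist, and the
first light of the sun touched the roofs of the small houses along the
track. A young woman opened her book and began to read, while an older man
across the aisle looked out at the passing countryside and thought about
the long day ahead of him. The weather had been unusually warm for this
time of year, and everyone was talking about the coming harvest and whether
the rain would arrive in time. In the town itself, the shops were opening
one by one. The baker set out fresh loaves of bread, the grocer arranged
boxes of apples and pears on the tables in front of his store, and the
children walked to school in small groups, laughing and calling to each
other across the street. It was an ordinary day, and yet there was
something pleasant about the quiet rhythm of it all, the sense that things
were happening in their proper order and at their proper time. Later in the
afternoon, when the heat of the day had passed, people would gather in the
square near the old fountain to talk about the news, about their families,
and about the little things that make up a life in a place where everyone
knows everyone else by name and by habit.
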