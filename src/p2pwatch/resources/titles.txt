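# Stand-in published-title database: one title per line.
# Replace with a full catalogue dump (books + music) for production scans.
The Abominable Snowman
Iron Crypt of the Heretics
The Haunted Lighthouse
New York, New York
The Winner Takes It All
Quick Recipe And Meal Ideas
36 Christmas Carols & Songs
Pride and Prejudice
Wuthering Heights
Great Expectations
A Tale of Two Cities
Moby Dick
The Count of Monte Cristo
Treasure Island
The Adventures of Tom Sawyer
Dracula
Frankenstein
The Picture of Dorian Gray
Jane Eyre
Sense and Sensibility
The War of the Worlds
The Time Machine
Twenty Thousand Leagues Under the Sea
Around the World in Eighty Days
The Call of the Wild
White Fang
Anne of Green Gables
Little Women
The Secret Garden
Peter Pan
Alice in Wonderland
Gulliver's Travels
Robinson Crusoe
Don Quixote
The Odyssey
The Iliad
Paradise Lost
Dancing Queen
Bohemian Rhapsody
Stairway to Heaven
Hotel California
Sweet Home Chicago
Greatest Hits Collection
Ultimate Party Mix
Complete Guide to Home Repair
Beginner's Guide to Chess
World Atlas of Wine
Encyclopedia of Gardening
Dictionary of Quotations
Cooking for Beginners
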