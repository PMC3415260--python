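Abby
Abigail
Ada
Adrey
Agnes
Agns
Alce
Alcia
Alica
Alice
Alicia
Alison
Allisn
Allison
Allson
Alma
Amanda
Amber
Ambr
Amie
Amnda
Amy
An
Ana
Andra
Andrea
Ane
Anette
Ange
Angela
Angie
Angla
Angy
Anie
Anita
Ann
Anna
Anne
Annette
Annie
Anntte
Anny
Anta
April
Aprl
Aria
Arlene
Arlne
Ashleie
Ashley
Ashly
Audreie
Audrey
Audry
Aurora
Ava
Avery
Babs
Barb
Barbara
Barbra
Batrice
Bbbie
Bbs
Bcca
Bcky
Beatrce
Beatrice
Beca
Becca
Beckie
Becky
Belinda
Bella
Belnda
Bernce
Bernice
Bertha
Besie
Besse
Bessie
Bessy
Beth
Betrice
Betsie
Betsy
Bettie
Betty
Bety
Beverlie
Beverly
Bevrly
Bilie
Bille
Billie
Billy
Blanche
Blinda
Bllie
Bnnie
Bobbe
Bobbie
Bobby
Bobie
Bonie
Bonne
Bonnie
Bonny
Brandi
Brandie
Brandy
Brb
Brbara
Brenda
Britany
Brittanie
Brittany
Brittny
Brnda
Brndy
Brnice
Brtha
Brttany
Bssie
Bth
Btsy
Btty
Bverly
Carie
Carl
Carla
Carle
Carline
Carlyn
Carmen
Carmn
Carol
Carole
Caroline
Carolne
Carolyn
Carre
Carrie
Carry
Casandra
Cassandra
Cassndra
Catherine
Catherne
Cathie
Cathrine
Cathy
Cecilia
Charlene
Charlne
Charlote
Charlotte
Charltte
Cheryl
Chloe
Chris
Christie
Christina
Christine
Christna
Christne
Christy
Chrlene
Chrlotte
Chrs
Chrstina
Chrstine
Chrsty
Chryl
Cindie
Cindy
Cladia
Claire
Clara
Clare
Clauda
Claudia
Clire
Clleen
Clra
Cludia
Cndy
Cnnie
Cnstance
Coleen
Colleen
Collen
Conie
Conne
Connie
Conny
Constance
Constnce
Cora
Cortney
Courtneie
Courtney
Courtny
Crla
Crmen
Crol
Crole
Croline
Crolyn
Crrie
Crystal
Crystl
Cssandra
Ctherine
Cthy
Curtney
Cyntha
Cynthia
Daisie
Daisy
Dana
Dane
Danelle
Dani
Daniele
Danielle
Danille
Danna
Danne
Darlene
Darlne
Dasy
Dawn
Dbbie
Dborah
Dbra
Deana
Deanna
Deb
Debbe
Debbie
Debby
Debie
Deborah
Deborh
Debra
Debrah
Delores
Delors
Delres
Denise
Denna
Dense
Diana
Diane
Dianne
Dina
Dine
Dinne
Disy
Dlores
Dna
Dni
Dnielle
Dnise
Dnna
Dolores
Dolors
Dolres
Dona
Donna
Dora
Doris
Dorothie
Dorothy
Dors
Dorthy
Dot
Dotie
Dotte
Dottie
Dotty
Dra
Dris
Drlene
Drothy
Dttie
Dwn
Edith
Edna
Edth
Eileen
Eilen
Ela
Elaine
Elane
Elanor
Eleanor
Eleanr
Eleen
Elen
Elenor
Elie
Eline
Eliza
Elizabeth
Elizabth
Elizbeth
Ella
Elle
Ellen
Ellie
Elln
Elly
Else
Elsie
Elsy
Elza
Elzabeth
Ema
Emilie
Emily
Emly
Emma
Erca
Erica
Erika
Erin
Erka
Ern
Esther
Esthr
Ethel
Ethl
Eunice
Eva
Evelyn
Evlyn
Faye
Felcia
Felica
Felicia
Flicia
Flo
Florence
Flornce
Flosie
Flosse
Flossie
Flossy
Flrence
Flssie
Frances
Francs
Frnces
Gadalupe
Gail
Gal
Geneva
Genva
Georga
Georgia
Geraldine
Geraldne
Gergia
Gerldine
Gertrde
Gertrude
Gil
Gina
Gladys
Gldys
Glenda
Glnda
Glora
Gloria
Glria
Gna
Gneva
Gorgia
Grace
Graldine
Grce
Greta
Grta
Grtrude
Guadalpe
Guadalupe
Guadlupe
Gudalupe
Gwendlyn
Gwendolyn
Gwndolyn
Hannah
Harriet
Hather
Hattie
Hazel
Hazl
Heather
Heathr
Hedi
Heidi
Helen
Heln
Hether
Hidi
Hilda
Hlda
Hlen
Hlly
Hollie
Holly
Holy
Hzel
Ida
Inez
Irene
Iris
Irma
Irne
Isabel
Isabella
Izzy
Jacke
Jackie
Jacky
Jacqeline
Jacqueline
Jacquelne
Jacquline
Jame
Jamie
Jamy
Jan
Jance
Jane
Janet
Janette
Janice
Janita
Jann
Janne
Jant
Jckie
Jcqueline
Jdith
Jdy
Jean
Jeane
Jeanete
Jeanette
Jeanne
Jeantte
Jen
Jena
Jenette
Jenie
Jenifer
Jenna
Jenne
Jennfer
Jennie
Jennifer
Jennifr
Jenny
Jeny
Jes
Jesica
Jesie
Jess
Jessca
Jesse
Jessica
Jessie
Jessy
Jil
Jill
Jlia
Jlie
Jll
Jmie
Jne
Jnet
Jnice
Jnna
Jnnie
Jnnifer
Jnny
Jo
Joan
Joane
Joann
Joanna
Joanne
Joie
Jon
Jonn
Jonne
Jose
Josephine
Josephne
Josie
Josphine
Josy
Joy
Joyce
Jsephine
Jsie
Jss
Jssica
Jssie
Juanita
Juanta
Judie
Judith
Judth
Judy
Jula
Jule
Julia
Julie
July
Junita
Jyce
Kaie
Karen
Karn
Kat
Kate
Katherine
Katherne
Kathie
Kathleen
Kathlen
Kathrine
Kathryn
Kathy
Katie
Katrina
Katrna
Katy
Kay
Kellie
Kelly
Kely
Kim
Kimberlie
Kimberly
Kimbrly
Kittie
Kitty
Kity
Klly
Kmberly
Kren
Kristen
Kristi
Kristin
Kristina
Kristn
Kristna
Krsten
Krstin
Krstina
Kte
Ktherine
Kthleen
Kthryn
Kthy
Ktie
Ktrina
Ktty
Lah
Lara
Laren
Larie
Laura
Laure
Lauren
Laurie
Laurn
Laury
Layla
Lbby
Lcille
Lcy
Leah
Leh
Leila
Lena
Leona
Lesle
Leslie
Lesly
Libbie
Libby
Liby
Lilian
Lilie
Lillan
Lille
Lillian
Lillie
Lillin
Lilly
Lily
Linda
Lindsaie
Lindsay
Lindseie
Lindsey
Lindsy
Lis
Lisa
Liz
Lizy
Lizzie
Lizzy
Lllian
Lllie
Lna
Lnda
Lndsay
Lndsey
Lois
Loise
Lona
Loraine
Loreta
Loretta
Lori
Lorraine
Lorrane
Lorrine
Lortta
Los
Louise
Louse
Lretta
Lri
Lrraine
Lsa
Lslie
Lucie
Lucile
Lucille
Luclle
Lucy
Luise
Lura
Luren
Lurie
Lyda
Lydia
Lyn
Lynda
Lynn
Lzzy
Mabel
Mabl
Madeline
Mae
Magge
Maggie
Maggy
Magie
Mandie
Mandy
Mara
Maran
Marca
Marcia
Mare
Mareen
Margaret
Margarita
Margart
Margarta
Marge
Margie
Margret
Margrita
Marguerite
Margy
Maria
Marian
Marie
Marilyn
Marin
Marion
Marjore
Marjorie
Marjory
Marjrie
Marlene
Marlne
Marlyn
Maron
Marsha
Martha
Mary
Matie
Matte
Mattie
Matty
Maureen
Mauren
Maxine
Maxne
Mbel
Mchele
Mchelle
Mdge
Meg
Megan
Megn
Mel
Melane
Melanie
Melany
Melinda
Melisa
Melissa
Melnda
Melnie
Melssa
Mgan
Mggie
Mia
Michele
Michelle
Michle
Michlle
Midge
Mildrd
Mildred
Minie
Minne
Minnie
Minny
Miram
Miriam
Mirim
Missie
Missy
Mistie
Misty
Misy
Mlanie
Mldred
Mlinda
Mlissa
Mndy
Mnica
Mnnie
Molly
Monca
Monica
Mrcia
Mrgaret
Mrgarita
Mrge
Mrgie
Mria
Mriam
Mrian
Mrie
Mrilyn
Mrion
Mrjorie
Mrlene
Mrsha
Mrtha
Mry
Mssy
Msty
Mttie
Mureen
Mxine
Myrtle
Nami
Nancie
Nancy
Naomi
Nat
Natale
Natalie
Nataly
Natasha
Natlie
Ncole
Nel
Nelie
Nell
Nelle
Nellie
Nelly
Nicle
Nicole
Nina
Nll
Nllie
Nna
Nncy
Nomi
Nora
Norma
Nra
Nrma
Ntalie
Olga
Olivia
Pala
Paline
Pam
Pamela
Pamla
Parl
Pat
Patrcia
Patrica
Patricia
Patsie
Patsy
Pattie
Patty
Paty
Paula
Pauline
Paulne
Pearl
Peggie
Peggy
Pegy
Pennie
Penny
Peny
Perl
Pggy
Phylis
Phyllis
Phylls
Pmela
Pnny
Priscila
Priscilla
Prisclla
Prscilla
Ptricia
Ptsy
Ptty
Pula
Puline
Rachel
Rachl
Ramna
Ramona
Rbecca
Rberta
Rbin
Rby
Rchel
Rebcca
Rebeca
Rebecca
Regina
Regna
Rene
Renee
Rgina
Rhnda
Rhonda
Rita
Rmona
Rnee
Rnnie
Roberta
Robin
Robn
Robrta
Ronie
Ronne
Ronnie
Ronny
Rosa
Rose
Rosemarie
Rosemary
Rosemry
Rosie
Rosmary
Rsa
Rse
Rsemary
Rta
Rth
Rubie
Ruby
Ruth
Sabrina
Sallie
Sally
Saly
Sam
Samantha
Sammie
Sammy
Samntha
Samy
Sandie
Sandra
Sandy
Sara
Sarah
Sarh
Savannah
Scarlett
Shannn
Shannon
Shanon
Sharn
Sharon
Sheila
Shela
Shellie
Shelly
Shely
Sheri
Sherri
Sherrie
Sherry
Shery
Sheryl
Shila
Shirleie
Shirley
Shirly
Shlly
Shnnon
Shrley
Shron
Shrri
Shrry
Shryl
Slly
Smantha
Smmy
Sndra
Sndy
Snia
Sona
Sonia
Sophia
Sra
Srah
Ssan
Ssie
Staceie
Stacey
Stacie
Stacy
Stcey
Stcy
Stela
Stella
Steph
Stephane
Stephanie
Stephany
Stephnie
Stlla
Stph
Stphanie
Sue
Susan
Suse
Susie
Susn
Susy
Suzane
Suzanne
Suzie
Suznne
Suzy
Sylva
Sylvia
Szanne
Szy
Tamara
Tammie
Tammy
Tamra
Tamy
Tanya
Tara
Teresa
Teri
Terri
Terrie
Terry
Tersa
Tery
Tffany
Thelma
Theresa
Thersa
Thlma
Thresa
Tifany
Tiffanie
Tiffany
Tiffny
Tina
Tmara
Tmmy
Tna
Tni
Tnya
Toni
Tonya
Tori
Tra
Traceie
Tracey
Tracie
Tracy
Trcey
Trcia
Trcy
Tresa
Tri
Trica
Tricia
Trish
Trri
Trry
Trsh
Valere
Valerie
Valery
Valrie
Vanesa
Vanessa
Vanssa
Vcki
Vckie
Vcky
Vctoria
Velma
Vera
Vernica
Veronca
Veronica
Vicke
Vicki
Vickie
Vicky
Victora
Victoria
Victria
Vila
Vilet
Viola
Violet
Violt
Virgina
Virginia
Virgnia
Vivan
Vivian
Vivin
Vlerie
Vlma
Vnessa
Vola
Volet
Vra
Vrginia
Vronica
Vvian
Wanda
Wendie
Wendy
Wilie
Wille
Willie
Willy
Wilma
Wllie
Wlma
Wnda
Wndy
Ylanda
Yolanda
Yolnda
Yvnne
Yvone
Yvonne
Zoe
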