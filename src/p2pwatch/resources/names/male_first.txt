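Aarn
Aaron
Adam
Adm
Adran
Adrian
Adrin
Aiden
Alan
Albert
Alberto
Albrt
Albrto
Alejandro
Alejndro
Alen
Alex
Alexander
Alexandr
Alexnder
Alfnso
Alfonso
Alfrd
Alfrdo
Alfred
Alfredo
Aljandro
Allan
Allen
Alln
Aln
Alvin
Alvn
Alx
Alxander
Andie
Andre
Andrew
Andrw
Andy
Angel
Angelo
Angl
Anglo
Ant
Anthny
Anthonie
Anthony
Antnio
Antonio
Antono
Armando
Armndo
Arnld
Arnold
Aron
Arthr
Arthur
Artro
Arturo
Barrie
Barry
Bary
Bbby
Ben
Benjamin
Benjamn
Benji
Benjmin
Bennie
Benny
Beny
Bernard
Bernrd
Bert
Bil
Bill
Billie
Billy
Bily
Bll
Blly
Bnjamin
Bnji
Bnny
Bob
Bobbie
Bobby
Boby
Brad
Bradleie
Bradley
Bradly
Bran
Brandn
Brandon
Brce
Brd
Brdley
Brent
Bret
Brett
Brian
Brin
Brnard
Brndon
Brnt
Brry
Brt
Brtt
Bruce
Bryan
Bryn
Byrn
Byron
Caleb
Calvin
Calvn
Camern
Cameron
Camron
Carl
Carlos
Carls
Carltn
Carlton
Carter
Caseie
Casey
Casy
Ccil
Cdy
Cecil
Cecl
Chad
Charle
Charles
Charlie
Charls
Charly
Chas
Chck
Chd
Chester
Chestr
Chris
Christan
Christian
Christin
Christopher
Christophr
Christpher
Chrles
Chrlie
Chrs
Chrstian
Chrstopher
Chs
Chster
Chuck
Clade
Clarence
Clarnce
Claude
Claytn
Clayton
Clfford
Clfton
Clifford
Cliffrd
Cliford
Cliftn
Clifton
Clintn
Clinton
Clnton
Clrence
Clude
Clvin
Clyde
Clyton
Cmeron
Codie
Cody
Connor
Coreie
Corey
Corie
Cory
Crag
Craig
Crey
Crig
Crl
Crlos
Crlton
Crtis
Cry
Csey
Curtis
Curts
Dale
Dan
Dana
Dane
Danel
Daniel
Danil
Dannie
Danny
Dany
Darell
Daren
Darrell
Darren
Darrll
Darrn
Darryl
Daryl
Davd
Dave
David
Dck
Dean
Den
Denis
Dennis
Denns
Derek
Derick
Derk
Derrck
Derrick
Dick
Dle
Dna
Dnald
Dniel
Dnnie
Dnnis
Dnny
Dog
Doglas
Don
Donald
Donie
Donld
Donne
Donnie
Donny
Dony
Doug
Douglas
Dougls
Drek
Drew
Drrell
Drren
Drrick
Drryl
Drw
Dryl
Dstin
Duane
Dug
Duglas
Dune
Dustin
Dustn
Dve
Dvid
Dwayne
Dwght
Dwight
Dwyne
Earl
Ed
Edardo
Edde
Eddie
Eddy
Edgar
Edgr
Edie
Eduardo
Edurdo
Edward
Edwin
Edwn
Edwrd
Egene
Elijah
Elmer
Elmr
Enriqe
Enrique
Enrque
Erc
Eric
Erik
Erk
Erl
Ernest
Ernesto
Ernst
Ernsto
Ethan
Eugene
Eugne
Evan
Everet
Everett
Evertt
Evn
Evrett
Felix
Felx
Fernando
Fernndo
Flix
Floyd
Flyd
Francis
Francisco
Francs
Francsco
Frank
Franklin
Frankln
Frd
Frddie
Frddy
Frderick
Frdrick
Fred
Fredde
Freddie
Freddy
Frederck
Frederick
Fredie
Fredrck
Fredrick
Fredy
Frnando
Frncis
Frncisco
Frnk
Frnklin
Gabrel
Gabriel
Gabril
Garie
Gary
Gavin
Gbriel
Gene
George
Gerald
Gerard
Gerge
Gerld
Gerrd
Gerrie
Gerry
Gery
Gilbert
Gilbrt
Glbert
Glen
Glenn
Gln
Glnn
Gne
Gordn
Gordon
Gorge
Grald
Grard
Grdon
Greg
Gregorie
Gregory
Gregry
Grg
Grgory
Grry
Gry
Guie
Guy
Harld
Harold
Harrie
Harry
Harveie
Harvey
Harvy
Hary
Hbert
Hctor
Hector
Hectr
Henrie
Henry
Herbert
Herbrt
Herman
Hermn
Hgh
Hmer
Hnry
Homer
Homr
Howard
Howrd
Hrbert
Hrman
Hrold
Hrry
Hrvey
Hubert
Hubrt
Hugh
Hunter
Hward
Ian
Isaac
Isac
Isaiah
Ivan
Ivn
Jacb
Jack
Jacke
Jackie
Jackson
Jacky
Jacob
Jaie
Jaime
Jake
Jame
James
Jamie
Jams
Jamy
Jan
Jard
Jared
Jasn
Jason
Javer
Javier
Javir
Jay
Jck
Jckie
Jcob
Jef
Jefery
Jeff
Jefferie
Jeffery
Jeffreie
Jeffrey
Jeffry
Jefrey
Jel
Jeremah
Jeremiah
Jeremie
Jeremih
Jeremy
Jerme
Jermiah
Jermy
Jerome
Jerrie
Jerry
Jery
Jese
Jesie
Jess
Jesse
Jessie
Jessy
Jesus
Jey
Jff
Jffery
Jffrey
Jhn
Jhnnie
Jhnny
Jim
Jime
Jimie
Jimme
Jimmie
Jimmy
Jimy
Jke
Jlian
Jlio
Jlius
Jmes
Jmie
Jmmie
Jmmy
Jnathan
Jnny
Joe
Joeie
Joel
Joey
John
Johnie
Johnne
Johnnie
Johnny
Johny
Jol
Jon
Jonathan
Jonathn
Jonnie
Jonny
Jonthan
Jony
Jordan
Jordn
Jorge
Jose
Joseph
Josh
Josha
Joshua
Josph
Joy
Jrdan
Jred
Jremiah
Jremy
Jrge
Jrome
Jrry
Jse
Jseph
Jsh
Jshua
Json
Jsse
Jssie
Jstin
Jsus
Juan
Julan
Julian
Julin
Julio
Julis
Julius
Julo
Julus
Jun
Justin
Justn
Jvier
Karl
Keith
Kellie
Kelly
Kely
Ken
Keneth
Kenneth
Kennie
Kennth
Kenny
Kent
Keny
Keth
Kevin
Kevn
Kirk
Kit
Kith
Klly
Knneth
Knny
Knt
Krk
Krl
Krt
Kurt
Kvin
Kyle
Lam
Lance
Landon
Larrie
Larry
Lary
Lawrence
Lawrnce
Lee
Len
Lenard
Leo
Leon
Leonard
Leonrd
Leroie
Leroy
Lery
Lesle
Leslie
Lesly
Lester
Lestr
Lewis
Lews
Lex
Liam
Lim
Lis
Lke
Lloyd
Llyd
Lnce
Lnnie
Logan
Lois
Lon
Lonard
Lonie
Lonne
Lonnie
Lonny
Lorenzo
Louis
Lous
Lroy
Lrry
Lslie
Lster
Lther
Lucas
Luis
Luke
Lus
Luther
Luthr
Lwis
Lwrence
Lyle
Lyn
Lynn
Manel
Manuel
Manul
Marc
Marcs
Marcus
Marice
Marin
Mario
Marion
Mark
Maro
Maron
Marshal
Marshall
Marshll
Martin
Martn
Marvin
Marvn
Mason
Mat
Mathew
Mathw
Matt
Matthew
Matthw
Mattie
Matty
Maty
Maurce
Maurice
Max
Mchael
Mcheal
Mck
Mckey
Meehai
Melvin
Melvn
Mguel
Michael
Michal
Micheal
Michel
Mick
Mickeie
Mickey
Micky
Migel
Miguel
Migul
Mike
Mikeie
Mikey
Miky
Miltn
Milton
Mitchel
Mitchell
Mitchll
Mke
Mkey
Mlton
Mlvin
Mnuel
Moris
Morris
Morrs
Mrc
Mrcus
Mrio
Mrion
Mrk
Mrris
Mrshall
Mrtin
Mrvin
Mtchell
Mthew
Mtt
Mtthew
Mtty
Murice
Nal
Nat
Nate
Nathan
Nathanel
Nathaniel
Nathanil
Nathn
Nathniel
Ncholas
Nck
Ncky
Neal
Ned
Neil
Nel
Nelsn
Nelson
Nichlas
Nicholas
Nichols
Nick
Nickie
Nicky
Nil
Nlson
Noah
Nolan
Norman
Normn
Nrman
Nte
Nthan
Nthaniel
Oliver
Olivr
Olver
Omar
Orlando
Orlndo
Oscar
Oscr
Otis
Ots
Owen
Pablo
Paddie
Paddy
Pady
Pal
Pat
Patrck
Patrick
Paul
Pblo
Pddy
Pdro
Pedro
Perrie
Perry
Pery
Pete
Peter
Petr
Philip
Phillip
Phillp
Philp
Phlip
Phllip
Prry
Pte
Pter
Ptrick
Pul
Rafael
Rafal
Rafel
Raie
Ral
Ralph
Ramn
Ramon
Randal
Randall
Randie
Randll
Randy
Raul
Ray
Raymnd
Raymond
Rbbie
Rben
Rbert
Rberto
Rcardo
Rch
Rchard
Rchie
Rck
Rcky
Rdney
Reginald
Reginld
Regnald
Rene
Rex
Rfael
Rger
Rginald
Ricardo
Rich
Richard
Riche
Richie
Richrd
Richy
Rick
Rickie
Ricky
Ricrdo
Rland
Rlph
Rmon
Rnald
Rndall
Rndy
Rne
Rnnie
Rob
Robbe
Robbie
Robby
Robert
Roberto
Robie
Robrt
Robrto
Rodneie
Rodney
Rodny
Roger
Rogr
Roie
Roland
Rolnd
Ron
Ronald
Ronie
Ronld
Ronne
Ronnie
Ronny
Ros
Ross
Roy
Rss
Rssell
Ruben
Rubn
Rul
Rusell
Russell
Russll
Ryan
Rymond
Ryn
Salvador
Salvadr
Salvdor
Sam
Samel
Sammie
Sammy
Samuel
Samul
Samy
San
Sasha
Scot
Scott
Sctt
Sdney
Sean
Sebastian
Sen
Sergio
Sergo
Seth
Shan
Shane
Shannn
Shannon
Shanon
Shaun
Shawn
Shne
Shnnon
Shun
Shwn
Sidneie
Sidney
Sidny
Slvador
Smmy
Smuel
Srgio
Ssha
Stanleie
Stanley
Stanly
Start
Stephen
Stephn
Steve
Steven
Stevie
Stevn
Stevy
Sth
Stnley
Stphen
Stuart
Sturt
Stve
Stven
Stvie
Tdd
Tddy
Ted
Teddie
Teddy
Tedy
Terance
Terence
Terrance
Terrence
Terrie
Terrnce
Terry
Tery
Thedore
Theo
Theodore
Theodre
Thmas
Tho
Thodore
Thomas
Thoms
Tim
Timmie
Timmy
Timothie
Timothy
Timthy
Timy
Tmmy
Tmothy
Tny
Tod
Todd
Tom
Tommie
Tommy
Tomy
Tonie
Tony
Topher
Tophr
Tpher
Tracie
Tracy
Travis
Travs
Trcy
Trevor
Trevr
Troie
Troy
Trrance
Trrence
Trry
Trvis
Trvor
Try
Tyler
Tylr
Tyrne
Tyrone
Vctor
Vernn
Vernon
Victor
Victr
Vincent
Vincnt
Virgil
Virgl
Vncent
Vrgil
Vrnon
Wade
Walace
Wallace
Wallce
Walter
Waltr
Waren
Warren
Warrn
Wayne
Wde
Wendel
Wendell
Wendll
Wesleie
Wesley
Wesly
Wil
Wilard
Wilbur
Wiliam
Wilie
Will
Willam
Willard
Wille
William
Willie
Willim
Willrd
Willy
Wily
Wll
Wllace
Wllard
Wlliam
Wllie
Wlly
Wlter
Wndell
Wrren
Wsley
Wyatt
Wyne
Xander
Xandr
Xnder
Zach
Zacharie
Zachary
Zachry
Zack
Zch
Zchary
Zck
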