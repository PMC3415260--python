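# Publishable-content identifiers: category<TAB>term, matched (with simple
# plural/singular variants) in the first 200 words of a file.
Books	ebook
Books	isbn
Books	copyright
Books	publisher
Books	paperback
Books	hardcover
Books	novel
Books	bestseller
Books	preface
Books	foreword
Education	thesis
Education	assignment
Education	homework
Education	dissertation
Education	essay
Education	syllabus
Education	coursework
Education	midterm
Education	bibliography
Retail	tim hortons
Retail	walmart
Retail	coupon
Retail	catalog
Retail	catalogue
Retail	advertisement
Retail	warranty
Retail	clearance sale
Periodical	magazine
Periodical	article
Periodical	newsletter
Periodical	editorial
Periodical	columnist
Periodical	tabloid
Fictional	harry porter
Fictional	harry potter
Fictional	bart simpson
Fictional	batman
Fictional	spiderman
Fictional	darth vader
Fictional	sherlock holmes
Fictional	frodo
Fictional	paris hilton
Fictional	britney spears
Politics	nicolas sarkozy
Politics	george bush
Politics	barack obama
Politics	stephen harper
Politics	tony blair
Politics	parliament
Politics	senator
Politics	referendum
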