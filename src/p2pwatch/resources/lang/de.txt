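Der Morgenzug verließ den Bahnhof mit einigen Minuten Verspätung, und die
Fahrgäste machten es sich mit Zeitungen und Kaffeetassen auf ihren Plätzen
bequem. Vor dem Fenster lagen die Felder noch unter einer dünnen Schicht
aus Nebel, und das erste Licht der Sonne berührte die Dächer der kleinen
Häuser entlang der Strecke. Eine junge Frau schlug ihr Buch auf und begann
zu lesen, während ein älterer Mann auf der anderen Seite des Ganges auf die
vorbeiziehende Landschaft hinausblickte und an den langen Tag dachte, der
vor ihm lag. Das Wetter war für diese Jahreszeit ungewöhnlich warm gewesen,
und alle sprachen über die kommende Ernte und fragten sich, ob der Regen
rechtzeitig kommen würde. In der Stadt selbst öffneten die Geschäfte eines
nach dem anderen. Der Bäcker stellte frische Brote heraus, der Händler
ordnete Kisten mit Äpfeln und Birnen auf den Tischen vor seinem Laden, und
die Kinder gingen in kleinen Gruppen zur Schule, lachten und riefen
einander über die Straße zu. Es war ein gewöhnlicher Tag, und doch lag
etwas Angenehmes in dem ruhigen Rhythmus des Ganzen, in dem Gefühl, dass
die Dinge in ihrer richtigen Ordnung und zu ihrer richtigen Zeit geschahen.
Später am Nachmittag, wenn die Hitze des Tages vorüber war, würden sich die
Leute auf dem Platz bei dem alten Brunnen versammeln, um über die
Neuigkeiten zu sprechen, über ihre Familien und über die kleinen Dinge, aus
denen das Leben an einem Ort besteht, wo jeder jeden mit Namen kennt.
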