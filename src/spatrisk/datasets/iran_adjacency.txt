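# Neighbour pairs for Iran's 30 pre-2010 provinces (2006 administrative map).
# Tehran includes present-day Alborz; Tabas is counted within Yazd.
# Hand-encoded from a public administrative map; structural properties
# (symmetry, connectivity, no self-loops) are test-asserted, individual
# edges are user-replaceable via any edge-list file of the same format.
east_azerbaijan	west_azerbaijan
east_azerbaijan	ardabil
east_azerbaijan	zanjan
west_azerbaijan	zanjan
west_azerbaijan	kordistan
ardabil	gilan
ardabil	zanjan
zanjan	gilan
zanjan	qazvin
zanjan	hamadan
zanjan	kordistan
gilan	qazvin
gilan	mazandaran
qazvin	hamadan
qazvin	markazi
qazvin	tehran
qazvin	mazandaran
mazandaran	tehran
mazandaran	semnan
mazandaran	golestan
tehran	markazi
tehran	qom
tehran	semnan
semnan	qom
semnan	esfahan
semnan	yazd
semnan	razavi_khorasan
semnan	north_khorasan
semnan	golestan
golestan	north_khorasan
north_khorasan	razavi_khorasan
razavi_khorasan	yazd
razavi_khorasan	south_khorasan
south_khorasan	yazd
south_khorasan	sistan
south_khorasan	kerman
esfahan	qom
esfahan	markazi
esfahan	lorestan
esfahan	khuzestan
esfahan	chaharmahal
esfahan	kohgiluyeh
esfahan	fars
esfahan	yazd
yazd	fars
yazd	kerman
fars	kerman
fars	hormozgan
fars	bushehr
fars	kohgiluyeh
kerman	hormozgan
kerman	sistan
hormozgan	bushehr
hormozgan	sistan
bushehr	khuzestan
bushehr	kohgiluyeh
kohgiluyeh	khuzestan
kohgiluyeh	chaharmahal
chaharmahal	khuzestan
chaharmahal	lorestan
khuzestan	ilam
khuzestan	lorestan
lorestan	ilam
lorestan	markazi
lorestan	hamadan
lorestan	kermanshah
ilam	kermanshah
kermanshah	kordistan
kermanshah	hamadan
kordistan	hamadan
hamadan	markazi
markazi	qom
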