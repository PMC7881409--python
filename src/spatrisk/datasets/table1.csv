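area,sex,observed,expected
east_azerbaijan,female,376,32.96
east_azerbaijan,male,476,43.87
west_azerbaijan,female,237,330.51
west_azerbaijan,male,302,63.80
ardabil,female,2028,192.51
ardabil,male,2612,251.02
esfahan,female,590,700.90
esfahan,male,799,949.62
ilam,female,27,84.22
ilam,male,48,113.27
bushehr,female,64,131.81
bushehr,male,85,190.32
tehran,female,2088,2055.28
tehran,male,2586,2806.18
chaharmahal,female,82,134.35
chaharmahal,male,120,175.52
south_khorasan,female,23,99.05
south_khorasan,male,27,130.99
razavi_khorasan,female,654,877.34
razavi_khorasan,male,845,1142.36
north_khorasan,female,37,129.13
north_khorasan,male,41,163.41
khuzestan,female,370,33.52
khuzestan,male,483,45.71
zanjan,female,69,152.20
zanjan,male,116,195.87
semnan,female,79,90.55
semnan,male,109,122.98
sistan,female,58,373.32
sistan,male,79,496.58
fars,female,391,671.95
fars,male,568,896.54
qazvin,female,109,176.29
qazvin,male,130,237.41
qom,female,86,160.68
qom,male,151,218.32
kordistan,female,110,223.91
kordistan,male,155,296.72
kerman,female,169,409.26
kerman,male,176,550.51
kermanshah,female,218,27.99
kermanshah,male,252,36.39
kohgiluyeh,female,38,98.75
kohgiluyeh,male,47,130.52
golestan,female,154,256.21
golestan,male,200,326.99
gilan,female,358,380.20
gilan,male,528,487.34
lorestan,female,125,265.64
lorestan,male,168,355.26
mazandaran,female,407,458.75
mazandaran,male,490,596.46
markazi,female,112,210.82
markazi,male,141,277.46
hormozgan,female,64,213.84
hormozgan,male,102,294.88
hamadan,female,136,266.77
hamadan,male,182,348.41
yazd,female,129,149.29
yazd,male,137,210.28
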