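>WINDOW_MASK
............*****...................
>seed01
GKSRLLEDFRNHNYVIQKFFEHGSPEQRRELADELA
>seed02
GRSRILEDFRNHNYVIQKFFEHGTPEQRRDLADELA
>seed03
GRSRLLEDYRNHNYVIQKFFQHGTPEQRRELAEELA
>seed04
ARSRLLEDFRNHNYVIQKFFEHGTPEQKRELADELA
>seed05
GRSRLLEDFRSHNYVIQKFFEHGTPEQRRELADEMA
>seed06
GRSRLVEDFRNHNYVMQKFFEHGTPEQRRELADELA
>seed07
GRSRLLEDFRNHCRVIQKFLEHGTPEQRRELADELA
>seed08
GRSQLLEDFRNHCRVIQKFFEHGTPDQRRELADELA
>seed09
GRSRLLEDFRNHSNVIEKFFEHATPEQRRELADELA
>seed10
GRSRLLEDFKNHSNVIEKFFEHGTPEQRREIADELA
>seed11
GRSRLLEDFRNHSYVIQKLFEHGTPEQRRELADELA
>seed12
GRSRLLEDFRNHSNVIRKFFEHGTPEQRRELADDLA
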