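device twoDPN
param arm = 12
param stem = 14
layer 1 membrane cut
default border=1.5 cut_stroke=0.2 margin=2
> id=junction shape=polygon points=-3.0,-2.0;3.0,-2.0;2.0,2.5;-2.0,2.5 layer=1
>> id=arm0 shape=rect len=arm w=3 angle=60 attach=abut layer=1
>>> id=inlet0 shape=circle d=6 angle=60 attach=abut layer=1
>> id=arm1 shape=rect len=arm w=3 angle=120 attach=abut layer=1
>>> id=inlet1 shape=circle d=6 angle=120 attach=abut layer=1
>> id=stem shape=rect len=stem w=3 angle=270 attach=abut layer=1
>>> id=sink shape=circle d=8 angle=270 attach=abut layer=1
> id=pad shape=rect len=12 w=8 angle=270 dist=40 layer=1
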