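device splitter1L
param arm = 6
layer 1 paper wax_buffered
default border=1.5 cut_stroke=0.2 margin=2
> id=center shape=circle d=4 layer=1
>> id=ch0 shape=rect len=arm w=1.2 angle=90 attach=abut layer=1
>>> id=zone0 shape=circle d=5 angle=90 attach=abut layer=1
>> id=ch1 shape=rect len=arm w=1.2 angle=210 attach=abut layer=1
>>> id=zone1 shape=circle d=5 angle=210 attach=abut layer=1
>> id=ch2 shape=rect len=arm w=1.2 angle=330 attach=abut layer=1
>>> id=zone2 shape=circle d=5 angle=330 attach=abut layer=1
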