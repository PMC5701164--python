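device origami
layer 1 paper wax_buffered
layer 2 paper wax_buffered
layer 3 paper wax_buffered
default border=1.5 cut_stroke=0.2 margin=2
> id=hub shape=circle d=4 layer=1
>> id=hub.c0 shape=rect len=5 w=1.5 attach=abut layer=1
>> id=hub.c1 shape=rect len=5 w=1.5 angle=90 attach=abut layer=1
>> id=hub.c2 shape=rect len=5 w=1.5 angle=180 attach=abut layer=1
>> id=hub.c3 shape=rect len=5 w=1.5 angle=270 attach=abut layer=1
> id=elbow shape=circle d=4 layer=2
>> id=elbow.c0 shape=rect len=6 w=1.5 attach=abut layer=2
>>> id=elbow.z shape=circle d=3 attach=abut layer=2
>> id=elbow.c1 shape=rect len=6 w=1.5 angle=90 attach=abut layer=2
> id=spoke shape=circle d=4 layer=3
>> id=spoke.c shape=rect len=6 w=1.5 angle=90 attach=abut layer=3
>>> id=spoke.z shape=circle d=3 angle=90 attach=abut layer=3
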