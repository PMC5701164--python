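device immunoassay3D
param lat = 10
layer 1 paper wax_buffered
layer 2 adhesive cut
layer 3 paper wax_buffered
layer 4 adhesive cut
layer 5 paper wax_buffered
layer 6 adhesive cut
layer 7 membrane wax_buffered
layer 8 adhesive cut
layer 9 paper wax_buffered
layer 10 adhesive cut
default border=1.5 cut_stroke=0.2 margin=2
> id=sample shape=circle d=5 layer=1
>> id=z3 shape=circle d=5 layer=3
>>> id=z5 shape=circle d=5 layer=5
>>>> id=z7 shape=circle d=5 layer=7
>>>>> id=z9 shape=circle d=5 layer=9
>>>>>> id=seal shape=circle d=3 layer=10
>>>> id=lateral shape=rect len=lat w=2 attach=abut layer=5
>>>>> id=lat_out shape=circle d=4 attach=abut layer=5
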