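device microzone96
layer 1 paper wax_full
default border=1.5 cut_stroke=0.2 margin=2
> id=A1 shape=circle d=6 angle=270 layer=1
>> id=lab_A shape=text text="A" h=3 angle=180 dist=9 layer=1
>> id=A2 shape=circle d=6 dist=9 layer=1
>>> id=A3 shape=circle d=6 dist=9 layer=1
>>>> id=A4 shape=circle d=6 dist=9 layer=1
>>>>> id=A5 shape=circle d=6 dist=9 layer=1
>>>>>> id=A6 shape=circle d=6 dist=9 layer=1
>>>>>>> id=A7 shape=circle d=6 dist=9 layer=1
>>>>>>>> id=A8 shape=circle d=6 dist=9 layer=1
>>>>>>>>> id=A9 shape=circle d=6 dist=9 layer=1
>>>>>>>>>> id=A10 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>> id=A11 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>> id=A12 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>>> id=lab_12 shape=text text="12" h=3 angle=90 dist=9 layer=1
>>>>>>>>>>>> id=lab_11 shape=text text="11" h=3 angle=90 dist=9 layer=1
>>>>>>>>>>> id=lab_10 shape=text text="10" h=3 angle=90 dist=9 layer=1
>>>>>>>>>> id=lab_9 shape=text text="9" h=3 angle=90 dist=9 layer=1
>>>>>>>>> id=lab_8 shape=text text="8" h=3 angle=90 dist=9 layer=1
>>>>>>>> id=lab_7 shape=text text="7" h=3 angle=90 dist=9 layer=1
>>>>>>> id=lab_6 shape=text text="6" h=3 angle=90 dist=9 layer=1
>>>>>> id=lab_5 shape=text text="5" h=3 angle=90 dist=9 layer=1
>>>>> id=lab_4 shape=text text="4" h=3 angle=90 dist=9 layer=1
>>>> id=lab_3 shape=text text="3" h=3 angle=90 dist=9 layer=1
>>> id=lab_2 shape=text text="2" h=3 angle=90 dist=9 layer=1
>> id=lab_1 shape=text text="1" h=3 angle=90 dist=9 layer=1
>> id=B1 shape=circle d=6 angle=270 dist=9 layer=1
>>> id=lab_B shape=text text="B" h=3 angle=180 dist=9 layer=1
>>> id=B2 shape=circle d=6 dist=9 layer=1
>>>> id=B3 shape=circle d=6 dist=9 layer=1
>>>>> id=B4 shape=circle d=6 dist=9 layer=1
>>>>>> id=B5 shape=circle d=6 dist=9 layer=1
>>>>>>> id=B6 shape=circle d=6 dist=9 layer=1
>>>>>>>> id=B7 shape=circle d=6 dist=9 layer=1
>>>>>>>>> id=B8 shape=circle d=6 dist=9 layer=1
>>>>>>>>>> id=B9 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>> id=B10 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>> id=B11 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>>> id=B12 shape=circle d=6 dist=9 layer=1
>>> id=C1 shape=circle d=6 angle=270 dist=9 layer=1
>>>> id=lab_C shape=text text="C" h=3 angle=180 dist=9 layer=1
>>>> id=C2 shape=circle d=6 dist=9 layer=1
>>>>> id=C3 shape=circle d=6 dist=9 layer=1
>>>>>> id=C4 shape=circle d=6 dist=9 layer=1
>>>>>>> id=C5 shape=circle d=6 dist=9 layer=1
>>>>>>>> id=C6 shape=circle d=6 dist=9 layer=1
>>>>>>>>> id=C7 shape=circle d=6 dist=9 layer=1
>>>>>>>>>> id=C8 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>> id=C9 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>> id=C10 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>>> id=C11 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>>>> id=C12 shape=circle d=6 dist=9 layer=1
>>>> id=D1 shape=circle d=6 angle=270 dist=9 layer=1
>>>>> id=lab_D shape=text text="D" h=3 angle=180 dist=9 layer=1
>>>>> id=D2 shape=circle d=6 dist=9 layer=1
>>>>>> id=D3 shape=circle d=6 dist=9 layer=1
>>>>>>> id=D4 shape=circle d=6 dist=9 layer=1
>>>>>>>> id=D5 shape=circle d=6 dist=9 layer=1
>>>>>>>>> id=D6 shape=circle d=6 dist=9 layer=1
>>>>>>>>>> id=D7 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>> id=D8 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>> id=D9 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>>> id=D10 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>>>> id=D11 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>>>>> id=D12 shape=circle d=6 dist=9 layer=1
>>>>> id=E1 shape=circle d=6 angle=270 dist=9 layer=1
>>>>>> id=lab_E shape=text text="E" h=3 angle=180 dist=9 layer=1
>>>>>> id=E2 shape=circle d=6 dist=9 layer=1
>>>>>>> id=E3 shape=circle d=6 dist=9 layer=1
>>>>>>>> id=E4 shape=circle d=6 dist=9 layer=1
>>>>>>>>> id=E5 shape=circle d=6 dist=9 layer=1
>>>>>>>>>> id=E6 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>> id=E7 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>> id=E8 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>>> id=E9 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>>>> id=E10 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>>>>> id=E11 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>>>>>> id=E12 shape=circle d=6 dist=9 layer=1
>>>>>> id=F1 shape=circle d=6 angle=270 dist=9 layer=1
>>>>>>> id=lab_F shape=text text="F" h=3 angle=180 dist=9 layer=1
>>>>>>> id=F2 shape=circle d=6 dist=9 layer=1
>>>>>>>> id=F3 shape=circle d=6 dist=9 layer=1
>>>>>>>>> id=F4 shape=circle d=6 dist=9 layer=1
>>>>>>>>>> id=F5 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>> id=F6 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>> id=F7 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>>> id=F8 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>>>> id=F9 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>>>>> id=F10 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>>>>>> id=F11 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>>>>>>> id=F12 shape=circle d=6 dist=9 layer=1
>>>>>>> id=G1 shape=circle d=6 angle=270 dist=9 layer=1
>>>>>>>> id=lab_G shape=text text="G" h=3 angle=180 dist=9 layer=1
>>>>>>>> id=G2 shape=circle d=6 dist=9 layer=1
>>>>>>>>> id=G3 shape=circle d=6 dist=9 layer=1
>>>>>>>>>> id=G4 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>> id=G5 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>> id=G6 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>>> id=G7 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>>>> id=G8 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>>>>> id=G9 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>>>>>> id=G10 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>>>>>>> id=G11 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>>>>>>>> id=G12 shape=circle d=6 dist=9 layer=1
>>>>>>>> id=H1 shape=circle d=6 angle=270 dist=9 layer=1
>>>>>>>>> id=lab_H shape=text text="H" h=3 angle=180 dist=9 layer=1
>>>>>>>>> id=H2 shape=circle d=6 dist=9 layer=1
>>>>>>>>>> id=H3 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>> id=H4 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>> id=H5 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>>> id=H6 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>>>> id=H7 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>>>>> id=H8 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>>>>>> id=H9 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>>>>>>> id=H10 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>>>>>>>> id=H11 shape=circle d=6 dist=9 layer=1
>>>>>>>>>>>>>>>>>>> id=H12 shape=circle d=6 dist=9 layer=1
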