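temperature,pH,time,activity
50,8,3,55.62
60,8,3,57.54
50,9,3,56.93
60,9,3,63.89
50,8.5,2,50.80
60,8.5,2,52.78
50,8.5,4,54.60
60,8.5,4,57.51
55,8,2,53.71
55,9,2,55.10
55,8,4,54.45
55,9,4,58.82
55,8.5,3,64.89
55,8.5,3,66.30
55,8.5,3,65.41
55,8.5,3,66.20
55,8.5,3,65.89
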