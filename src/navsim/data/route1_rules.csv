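here,goal,attention_label,next_step
1,6,with,2
1,6,without,7
2,6,with,3
2,6,without,8
3,6,with,4
3,6,without,9
4,6,with,5
4,6,without,10
5,6,with,6
5,6,without,11
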