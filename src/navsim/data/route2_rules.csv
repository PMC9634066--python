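here,goal,attention_label,next_step
4,1,with,3
4,1,without,10
3,1,with,2
3,1,without,9
2,1,with,1
2,1,without,8
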