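video,cname,manual,predicted
1,normal,169,163
1,buried_seedling,18,20
1,bare_root,9,8
2,normal,32,32
2,buried_seedling,1,1
2,bare_root,0,0
3,normal,59,59
3,buried_seedling,8,8
3,bare_root,17,15
4,normal,149,139
4,buried_seedling,27,31
4,bare_root,9,8
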