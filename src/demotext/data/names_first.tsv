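# Synthetic first-name gender table (fixture): name <TAB> label <TAB> share.
# Stand-in with made-up shares in the layout of an SSA baby-name export;
# a real conversion drops in unchanged.
james	male	0.996
james	female	0.004
john	male	0.995
john	female	0.005
robert	male	0.997
robert	female	0.003
michael	male	0.994
michael	female	0.006
david	male	0.996
david	female	0.004
mary	female	0.997
mary	male	0.003
patricia	female	0.996
patricia	male	0.004
jennifer	female	0.995
jennifer	male	0.005
linda	female	0.997
linda	male	0.003
elizabeth	female	0.996
elizabeth	male	0.004
taylor	female	0.55
taylor	male	0.45
jordan	male	0.70
jordan	female	0.30
casey	female	0.59
casey	male	0.41
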