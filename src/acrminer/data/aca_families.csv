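family
Aca1
Aca2
Aca3
Aca4
Aca5
Aca6
Aca7
Aca8
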