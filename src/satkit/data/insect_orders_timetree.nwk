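((((Coleoptera:327,(Lepidoptera:295,Diptera:295):32):13,Hymenoptera:340):20,Hemiptera:360):20,Blattodea:380);
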