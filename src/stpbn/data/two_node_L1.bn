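# Simplest reachable 2-node network (canonical form L1).
x1 = !x2
x2 = x1
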