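# Lower-triangle 3-node template: reachable 2-node base plus a
# controlled third node carrying the input u.
input u
x1 = !x2
x2 = x1
x3 = u
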