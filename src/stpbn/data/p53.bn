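# Major switch of the p53 pathway: ATM, p53, Wip1, Mdm2.
# ATM is inhibited by Wip1; p53 is promoted by ATM and inhibited by Mdm2;
# Wip1 is promoted by p53; Mdm2 is inhibited by ATM and promoted by p53/Wip1.
ATM = !Wip1
p53 = ATM & !Mdm2
Wip1 = p53
Mdm2 = !ATM & (p53 | Wip1)
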