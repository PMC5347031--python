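>M6WT synthetic stand-in for the myosin-6 SAH segment (97-residue core + S/W caps); matches the construct's length, %R=19, %K=11, %E=30 and 12.5 kDa monomer mass
SEQERRAEKLQEAERKLERMTEDERKIERNQEAEKRLERQAELEKRMEKTDEIERRQEKA
LEQERKAERLQEAERKLERQAELERKQERALEQEKRERW
>M6K synthetic stand-in, all Arg of M6WT replaced by Lys; %K=30, 12.0 kDa
SEQEKKAEKLQEAEKKLEKMTEDEKKIEKNQEAEKKLEKQAELEKKMEKTDEIEKKQEKA
LEQEKKAEKLQEAEKKLEKQAELEKKQEKALEQEKKEKW
>M6R synthetic stand-in, all Lys of M6WT replaced by Arg; %R=30, 12.8 kDa
SEQERRAERLQEAERRLERMTEDERRIERNQEAERRLERQAELERRMERTDEIERRQERA
LEQERRAERLQEAERRLERQAELERRQERALEQERRERW
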