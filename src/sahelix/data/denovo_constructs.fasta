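>EK3 de novo SAH design, repeat AEEEKKK, 98 aa (S cap + 96-residue core + W cap)
SAEEEKKKAEEEKKKAEEEKKKAEEEKKKAEEEKKKAEEEKKKAEEEKKKAEEEKKKAEE
EKKKAEEEKKKAEEEKKKAEEEKKKAEEEKKKAEEEKW
>ER3 de novo SAH design, repeat AEEERRR, 98 aa (S cap + 96-residue core + W cap)
SAEEERRRAEEERRRAEEERRRAEEERRRAEEERRRAEEERRRAEEERRRAEEERRRAEE
ERRRAEEERRRAEEERRRAEEERRRAEEERRRAEEERW
>EK2R1 de novo SAH design, repeat AEEEKRK, 98 aa (S cap + 96-residue core + W cap)
SAEEEKRKAEEEKRKAEEEKRKAEEEKRKAEEEKRKAEEEKRKAEEEKRKAEEEKRKAEE
EKRKAEEEKRKAEEEKRKAEEEKRKAEEEKRKAEEEKW
>EK1R2 de novo SAH design, repeat AEEEKRR, 98 aa (S cap + 96-residue core + W cap)
SAEEEKRRAEEEKRRAEEEKRRAEEEKRRAEEEKRRAEEEKRRAEEEKRRAEEEKRRAEE
EKRRAEEEKRRAEEEKRRAEEEKRRAEEEKRRAEEEKW
>EK2 de novo SAH design, repeat AEEAKKA, 98 aa (S cap + 96-residue core + W cap)
SAEEAKKAAEEAKKAAEEAKKAAEEAKKAAEEAKKAAEEAKKAAEEAKKAAEEAKKAAEE
AKKAAEEAKKAAEEAKKAAEEAKKAAEEAKKAAEEAKW
>EK1 de novo SAH design, repeat AAEAAKA, 98 aa (S cap + 96-residue core + W cap)
SAAEAAKAAAEAAKAAAEAAKAAAEAAKAAAEAAKAAAEAAKAAAEAAKAAAEAAKAAAE
AAKAAAEAAKAAAEAAKAAAEAAKAAAEAAKAAAEAAW
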