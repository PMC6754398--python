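# Desensitized-only gating scheme: the cross-linked receptor.
#
# The disulfide-locked ligand-binding-domain dimer can only occupy
# desensitized conformations, so the closed and open states of scheme 1 are
# removed.  What remains is the desensitized binding row (D0-D4*) and the
# deep desensitized row; because occupied desensitized states conduct, the
# scheme still responds to glutamate -- with a non-decaying current of
# reduced amplitude.

name = scheme2

[rates]
k1 = 1.3e6
k_minus1 = 350
alpha = 3100
beta = 1000
gamma1 = 88
delta1 = 110
gamma2 = 36
delta2 = 39
gamma0 = 8
delta0 = 0.48
k_minus2 = 870

[states]
D0         0        desensitized
D1*        1        desensitized
D2*        2        desensitized
D3*        3        desensitized
D4*        4        desensitized
D2_2*      2        deep_desensitized
D2_3*      3        deep_desensitized
D2_4*      4        deep_desensitized

[transitions]
D2*       D2_2*   delta2     2     -
D2_2*     D2*     gamma2     1     -
D3*       D2_3*   delta2     2     -
D2_3*     D3*     gamma2     1     -
D4*       D2_4*   delta2     2     -
D2_4*     D4*     gamma2     1     -
D0        D1*     k1         4     c
D1*       D0      k_minus2   1     -
D1*       D2*     k1         3     c
D2*       D1*     k_minus2   1     -
D2*       D3*     k1         2     c
D3*       D2*     k_minus2   1     -
D3*       D4*     k1         1     c
D4*       D3*     k_minus2   1     -

[conductances]
g_open_max = 3.9e-12
g_des_max = 670e-15
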