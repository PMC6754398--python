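# Gating scheme for the edited GluA2/gamma-2 AMPA receptor with conducting
# desensitized states.
#
# Layout: a closed row C0-C4 (0-4 glutamates bound) with sequential binding;
# each liganded closed state opens to O1-O4 (opening rate scaled by the
# number of bound agonists); open states desensitize to D1*-D4* without the
# pore shutting fully (entry scaled by occupancy, exit gamma1 to the open
# state); occupied desensitized states can relax further into a deep
# desensitized row D2_2*-D2_4* (both lobes of the dimer-of-dimers relaxed,
# statistical factor 2 on entry); the unliganded receptor has a small
# resting desensitized pool D0; glutamate dissociates within the
# desensitized row one site at a time with rate k_minus2.
#
# Conducting states: O1-O4 (up to 3.9 pS), D1*-D4* and D2_2*-D2_4*
# (up to 670 fS), scaled by n_bound/4.

name = scheme1

[rates]
k1 = 1.3e6          # M^-1 s^-1, glutamate association (per free site)
k_minus1 = 350      # s^-1, dissociation from closed states (per bound site)
alpha = 3100        # s^-1, channel closing
beta = 1000         # s^-1, channel opening (per bound agonist)
gamma1 = 88         # s^-1, exit from desensitization (to the open state)
delta1 = 110        # s^-1, desensitization entry (per bound agonist)
gamma2 = 36         # s^-1, exit from deep desensitization
delta2 = 39         # s^-1, deep desensitization entry (per relaxable lobe)
gamma0 = 8          # s^-1, resting desensitization exit
delta0 = 0.48       # s^-1, resting desensitization entry
k_minus2 = 870      # s^-1, dissociation within desensitized rows

[states]
# name     n_bound  class
C0         0        closed
C1         1        closed
C2         2        closed
C3         3        closed
C4         4        closed
O1         1        open
O2         2        open
O3         3        open
O4         4        open
D0         0        desensitized
D1*        1        desensitized
D2*        2        desensitized
D3*        3        desensitized
D4*        4        desensitized
D2_2*      2        deep_desensitized
D2_3*      3        deep_desensitized
D2_4*      4        deep_desensitized

[transitions]
# source  target  rate       mult  flag (c = concentration-dependent)
# glutamate binding along the closed row
C0        C1      k1         4     c
C1        C0      k_minus1   1     -
C1        C2      k1         3     c
C2        C1      k_minus1   2     -
C2        C3      k1         2     c
C3        C2      k_minus1   3     -
C3        C4      k1         1     c
C4        C3      k_minus1   4     -
# channel opening (rate grows with occupancy) and closing
C1        O1      beta       1     -
O1        C1      alpha      1     -
C2        O2      beta       2     -
O2        C2      alpha      1     -
C3        O3      beta       3     -
O3        C3      alpha      1     -
C4        O4      beta       4     -
O4        C4      alpha      1     -
# desensitization of the open channel (pore does not shut fully)
O1        D1*     delta1     1     -
D1*       O1      gamma1     1     -
O2        D2*     delta1     2     -
D2*       O2      gamma1     1     -
O3        D3*     delta1     3     -
D3*       O3      gamma1     1     -
O4        D4*     delta1     4     -
D4*       O4      gamma1     1     -
# deep desensitization (second dimer interface relaxes)
D2*       D2_2*   delta2     2     -
D2_2*     D2*     gamma2     1     -
D3*       D2_3*   delta2     2     -
D2_3*     D3*     gamma2     1     -
D4*       D2_4*   delta2     2     -
D2_4*     D4*     gamma2     1     -
# resting desensitization of the unliganded receptor
C0        D0      delta0     1     -
D0        C0      gamma0     1     -
# glutamate binding within the desensitized row; dissociation k_minus2
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

[reversibility]
# Balance of the monoliganded activation/desensitization/dissociation loop;
# evaluates to 868 s^-1 with the rates above (870 at two figures).
k_minus2 = k_minus1 * alpha * gamma1 / (beta * delta1)
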