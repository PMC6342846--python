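"""Published implicit descriptions of the two-state (CFN) model on the
rooted claw tree, one system per root case, in probability coordinates.

These are the reference systems the generator is checked against:
three quadric invariants, the sum-to-one equation, seven linear
Fourier-positivity constraints (strict, or partly equations in the
uniform case) and one cleared quadric inequality per edge.
"""

# fmt: off
CASE1_EQUATIONS = [
    "p001*p010 - p000*p011 + p001*p100 - p000*p101 - p011*p110 - p101*p110 + p010*p111 + p100*p111",
    "p001*p010 - p000*p011 + p010*p100 - p011*p101 - p000*p110 - p101*p110 + p001*p111 + p100*p111",
    "p001*p100 + p010*p100 - p000*p101 - p011*p101 - p000*p110 - p011*p110 + p001*p111 + p010*p111",
    "p000 + p001 + p010 + p011 + p100 + p101 + p110 + p111 - 1",
]

_LIN = {
    "001": "p000 - p001 + p010 - p011 + p100 - p101 + p110 - p111",
    "010": "p000 + p001 - p010 - p011 + p100 + p101 - p110 - p111",
    "011": "p000 - p001 - p010 + p011 + p100 - p101 - p110 + p111",
    "100": "p000 + p001 + p010 + p011 - p100 - p101 - p110 - p111",
    "101": "p000 - p001 + p010 - p011 - p100 + p101 - p110 + p111",
    "110": "p000 + p001 - p010 - p011 - p100 - p101 + p110 + p111",
    "111": "p000 - p001 - p010 + p011 - p100 + p101 + p110 - p111",
}

CASE1_STRICT = [_LIN[k] for k in ("001", "010", "011", "100", "101", "110", "111")]

CASE1_NONSTRICT = [
    "-p010*p100 - p011*p100 - p010*p101 - p011*p101 + p000*p110 + p001*p110 + p000*p111 + p001*p111",
    "-p001*p010 + p000*p011 + p000*p100 - p001*p101 - p010*p110 - p101*p110 + p011*p111 + p100*p111",
    "p000*p010 - p001*p011 - p001*p100 + p000*p101 - p011*p110 - p100*p110 + p010*p111 + p101*p111",
    # note: the sign of p011*p101 is forced by the exact expansion of the
    # cleared Fourier-level quotient q000*q110 - q101*q011; the published
    # rendering of this polynomial carries a typographical sign error there
    "p000*p001 - p010*p011 - p010*p100 - p011*p101 - p100*p101 + p000*p110 + p001*p111 + p110*p111",
]

# the state-swapped case: identical equations and quadric inequalities,
# with the odd-parity linear constraints reversed
CASE2_EQUATIONS = list(CASE1_EQUATIONS)
CASE2_STRICT = [
    "-(%s)" % _LIN["001"],
    "-(%s)" % _LIN["010"],
    _LIN["011"],
    "-(%s)" % _LIN["100"],
    _LIN["101"],
    _LIN["110"],
    "-(%s)" % _LIN["111"],
]
CASE2_NONSTRICT = list(CASE1_NONSTRICT)

# the uniform-root case: odd-parity linear forms become equations and the
# hidden-root-edge inequality disappears
CASE3_EQUATIONS = CASE1_EQUATIONS + [_LIN["001"], _LIN["010"], _LIN["100"], _LIN["111"]]
CASE3_STRICT = [_LIN["011"], _LIN["101"], _LIN["110"]]
CASE3_NONSTRICT = CASE1_NONSTRICT[1:]

# the q-coordinate inequality set for the biased-to-zero case, cleared
CASE1_Q_NONSTRICT = [
    "q000*q110 - q100*q010",
    "q000*q011 - q110*q101",
    "q000*q101 - q110*q011",
    "q000*q110 - q101*q011",
]
# fmt: on
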