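"""Shared constants: the ordered lens compartments and their adjacency."""

#: Ordered differentiation compartments: central epithelium, equatorial
#: epithelium, cortical (peripheral) fibers, central (nuclear) fibers.
COMPARTMENTS: tuple[str, ...] = ("EC", "EQ", "FP", "FC")

#: The three developmentally adjacent comparisons.
ADJACENT_PAIRS: tuple[tuple[str, str], ...] = (
    ("EC", "EQ"),
    ("EQ", "FP"),
    ("FP", "FC"),
)


def pair_name(c1: str, c2: str) -> str:
    return f"{c1}-{c2}"
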