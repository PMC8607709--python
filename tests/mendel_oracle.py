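"""Independent brute-force transmission oracle used by the test suite.

Enumerates the 2x2 ordered transmissions (which of the father's two alleles
is passed x which of the mother's two) directly and keeps those whose
multiset reproduces the child's genotype — deliberately a different
formulation from the engine's candidate-ordering approach.
"""

from collections import Counter
from typing import Optional


def brute_force_phase(
    child: tuple[int, int],
    father: Optional[tuple[int, int]],
    mother: Optional[tuple[int, int]],
) -> tuple[str, Optional[tuple[int, int]], bool]:
    """Return (status, phase, novel_allele) with status in
    {"phased", "unphaseable", "inconsistent"}.

    A missing parent transmits "anything", modelled by letting that side
    range over the child's own alleles.
    """
    paternal_options = father if father is not None else child
    maternal_options = mother if mother is not None else child
    child_multiset = Counter(child)
    valid = {
        (p, m)
        for p in paternal_options
        for m in maternal_options
        if Counter((p, m)) == child_multiset
    }
    novel = (
        father is not None
        and mother is not None
        and any(a not in set(father) | set(mother) for a in child)
    )
    if len(valid) == 1:
        return ("phased", next(iter(valid)), False)
    if not valid:
        return ("inconsistent", None, novel)
    return ("unphaseable", None, False)
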