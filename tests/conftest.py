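"""Shared fixtures: deterministic amplicon/pegRNA specs on a 200-nt locus."""

import numpy as np
import pytest

from crisprtox.amplicon import AmpliconSpec, PegSpec

# protospacer with three editable Cs in the default [4, 8] window
PROTOSPACER = "GATCCACTGATGTCAATGGA"
PAM = "AGG"


def _flank(seed: int, n: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


REFERENCE = _flank(11, 90) + PROTOSPACER + PAM + _flank(13, 87)
PROTO_START = 90


@pytest.fixture(scope="session")
def reference():
    return REFERENCE


@pytest.fixture(scope="session")
def cbe_spec():
    """CBE target: C→T conversion, editable Cs at protospacer 4, 5, 7."""
    return AmpliconSpec(reference=REFERENCE, protospacer_start=PROTO_START,
                        conversion=("C", "T"))


@pytest.fixture(scope="session")
def cas9_spec():
    """Nuclease target: same geometry, no programmed conversion."""
    return AmpliconSpec(reference=REFERENCE, protospacer_start=PROTO_START,
                        conversion=None)


@pytest.fixture(scope="session")
def peg_spec():
    """PE3 target: 2-nt substitution 3 nt past the pegRNA nick, plus a
    second nick 40 nt downstream on the opposite strand."""
    base = AmpliconSpec(reference=REFERENCE, protospacer_start=PROTO_START,
                        conversion=None)
    s = base.cut + 3
    ref_block = REFERENCE[s:s + 2]
    alt = "".join({"A": "C", "C": "A", "G": "T", "T": "G"}[b]
                  for b in ref_block)
    nick2_start = PROTO_START + 40
    # second protospacer on the minus strand (geometry only)
    nick_gRNA = AmpliconSpec(reference=REFERENCE,
                             protospacer_start=nick2_start,
                             protospacer_strand="-", conversion=None)
    return PegSpec(base=base, intended_edit=(s, s + 2, alt),
                   scaffold_prefix="GCACCGAGTCGG", nick_gRNA=nick_gRNA)
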