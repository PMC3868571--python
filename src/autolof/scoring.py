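"""Functional-ablation scoring of confirmed LoF alleles (0-3).

The score captures how likely a homozygous LoF allele is to fully ablate
the gene product, from two observable properties:

* **A** - the variant hits every annotated transcript of the gene (no
  unaffected alternative transcript can supply the product);
* **E** - the variant lands early enough in the open reading frame, i.e.
  outside the final ``tail_fraction`` (default 10%) of the CDS.

Score 3 requires both, score 1 is given when both fail (an unaffected
alternative transcript exists AND the change only affects the ORF tail),
and score 2 covers the single-failure middle ground. A variant carrying a
disqualifying flag (rescue interaction or reference-artifact signature)
scores 0. Positions exactly at the tail boundary count as body
(``pos_in_cds <= 1 - tail_fraction``).
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .core import DataError
from .discovery import (
    FLAG_REFERENCE_ARTIFACT,
    FLAG_RESCUED_COMPLEMENTARY,
    FLAG_RESCUED_SAME_CODON,
    LofCall,
    pos_in_cds_fraction as pos_in_cds,  # noqa: F401  (re-export)
)

DISQUALIFYING_FLAGS = frozenset(
    {FLAG_RESCUED_COMPLEMENTARY, FLAG_RESCUED_SAME_CODON, FLAG_REFERENCE_ARTIFACT}
)


@dataclass
class ScoreInputs:
    affects_all_transcripts: bool
    pos_in_cds: float
    disqualifying_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not 0.0 <= self.pos_in_cds <= 1.0:
            raise DataError(f"pos_in_cds {self.pos_in_cds} outside [0, 1]")


def score_lof(s: ScoreInputs, tail_fraction: float = 0.10) -> int:
    """Integer ablation score: 3 strongest, 1 weakest, 0 disqualified."""
    if s.disqualifying_flags & DISQUALIFYING_FLAGS:
        return 0
    early = s.pos_in_cds <= 1.0 - tail_fraction
    if s.affects_all_transcripts and early:
        return 3
    if not s.affects_all_transcripts and not early:
        return 1
    return 2


def score_table(table: list[LofCall], tail_fraction: float = 0.10) -> list[LofCall]:
    """Fill the ``score`` field of every call in place; returns the list."""
    for call in table:
        call.score = score_lof(
            ScoreInputs(
                affects_all_transcripts=call.affects_all_transcripts,
                pos_in_cds=call.pos_in_cds,
                disqualifying_flags=frozenset(call.flags),
            ),
            tail_fraction=tail_fraction,
        )
    return table
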