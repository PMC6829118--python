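"""In-silico PCR for breakpoint genotyping.

Two assays distinguish the three genotypes of a reciprocal translocation:
a wild-type assay whose primers flank a breakpoint on the intact
chromosome (amplifies WT and heterozygote templates, not the derivatives,
whose primer sites are separated onto different molecules), and a junction
assay with one primer on each side of a fusion junction (amplifies carrier
templates only).  Primer matching is exact -- this module validates assay
logic, not hybridization chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .synthetic_genome import ReferenceSet, revcomp

_ACGT = set("ACGT")

WT = "WT"
HET = "T/+"
HOM = "T/T"


class PcrError(ValueError):
    pass


@dataclass(frozen=True)
class PrimerPair:
    """A PCR assay; ``rev`` is given 5'->3' as synthesized."""

    name: str
    fwd: str
    rev: str
    max_product: int = 2000

    def __post_init__(self) -> None:
        for primer in (self.fwd, self.rev):
            if not 15 <= len(primer) <= 35:
                raise PcrError(f"{self.name!r}: primer length must be 15-35 nt")
            if set(primer) - _ACGT:
                raise PcrError(f"{self.name!r}: ambiguity codes not supported")


@dataclass
class AmpliconPrediction:
    """Products of one assay on one template; coordinates 1-based inclusive."""

    template_name: str
    products: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def present(self) -> bool:
        return bool(self.products)


def _find_all(hay: str, needle: str) -> list[int]:
    out, t = [], hay.find(needle)
    while t != -1:
        out.append(t)
        t = hay.find(needle, t + 1)
    return out


def predict_amplicons(pair: PrimerPair,
                      templates: ReferenceSet) -> list[AmpliconPrediction]:
    """Exact-match amplicons of ``pair`` on every template sequence."""
    rev_site = revcomp(pair.rev)
    out = []
    for name, seq in templates.items():
        pred = AmpliconPrediction(name)
        fwd_hits = _find_all(seq, pair.fwd)
        rev_hits = _find_all(seq, rev_site)
        for f in fwd_hits:
            for r in rev_hits:
                end = r + len(rev_site)
                length = end - f
                if r >= f and length <= pair.max_product:
                    pred.products.append((f + 1, end, length))
        out.append(pred)
    return out


def genotype(wt_present: bool, junction_present: bool) -> str:
    """Map the two-assay presence pattern to a genotype label."""
    if wt_present and junction_present:
        return HET
    if wt_present:
        return WT
    if junction_present:
        return HOM
    raise PcrError("assay failure: neither amplicon present")


def genotype_template_set(wt_assay: PrimerPair, junction_assay: PrimerPair,
                          templates: ReferenceSet) -> str:
    """Run both assays on one sample's template set and call the genotype."""
    wt_present = any(p.present for p in predict_amplicons(wt_assay, templates))
    jxn_present = any(p.present for p in predict_amplicons(junction_assay, templates))
    return genotype(wt_present, jxn_present)


def design_flanking_pair(seq: str, breakpoint: int, name: str,
                         primer_len: int = 22, offset: int = 60,
                         max_product: int = 2000) -> PrimerPair:
    """Primers flanking ``breakpoint`` on ``seq`` by ``offset`` nt each side."""
    f0 = breakpoint - offset - primer_len
    r0 = breakpoint + offset
    if f0 < 0 or r0 + primer_len > len(seq):
        raise PcrError("breakpoint too close to template end for requested flanks")
    return PrimerPair(name, seq[f0:f0 + primer_len],
                      revcomp(seq[r0:r0 + primer_len]), max_product)


def predictions_frame(pair: PrimerPair,
                      predictions: Sequence[AmpliconPrediction]) -> pd.DataFrame:
    rows = []
    for p in predictions:
        if p.products:
            for start, end, length in p.products:
                rows.append((pair.name, p.template_name, start, end, length))
        else:
            rows.append((pair.name, p.template_name, pd.NA, pd.NA, pd.NA))
    return pd.DataFrame(rows, columns=["assay", "template", "start", "end", "length"])


def read_primer_table(path) -> list[PrimerPair]:
    df = pd.read_csv(path, sep="\t")
    return [PrimerPair(str(r["name"]), str(r["fwd"]), str(r["rev"]))
            for _, r in df.iterrows()]
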