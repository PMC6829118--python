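"""BAC-FISH breakpoint narrowing.

Metaphase FISH with large-insert (BAC) probes classifies each probe as
lying entirely proximal to a translocation breakpoint, entirely distal, or
split by it (signal on both derivative chromosomes).  Inverting those
classifications yields the smallest interval of inter-base positions
consistent with every probe -- the in-silico analogue of narrowing a
breakpoint to the overlap region of split clones.

Positions are 0-based inter-base coordinates: a breakpoint ``bp`` sits
between reference bases ``bp - 1`` and ``bp``.  A probe touching the
breakpoint only at one of its endpoints is not split (FISH cannot resolve
boundary contact), so probe interiors are open intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PROXIMAL = "proximal"
DISTAL = "distal"
SPLIT = "split"
LABELS = (PROXIMAL, DISTAL, SPLIT)


class PanelError(ValueError):
    pass


@dataclass(frozen=True)
class Probe:
    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise PanelError(f"probe {self.name!r}: start must be < end")


@dataclass(frozen=True)
class ProbePanel:
    probes: tuple[Probe, ...]
    classifications: dict[str, str]

    def __post_init__(self) -> None:
        chroms = {p.chrom for p in self.probes}
        if len(chroms) > 1:
            raise PanelError(f"panel mixes chromosomes: {sorted(chroms)}")
        for p in self.probes:
            label = self.classifications.get(p.name)
            if label not in LABELS:
                raise PanelError(f"probe {p.name!r} missing or invalid label: {label!r}")

    @property
    def chrom(self) -> str:
        return self.probes[0].chrom


def classify_probe(probe: Probe, bp: int, chrom: str | None = None) -> str:
    """Three-way classification of a probe against an inter-base breakpoint."""
    if chrom is not None and chrom != probe.chrom:
        raise PanelError(f"breakpoint on {chrom!r} but probe on {probe.chrom!r}")
    if probe.start < bp < probe.end:
        return SPLIT
    if probe.end <= bp:
        return PROXIMAL
    return DISTAL


@dataclass(frozen=True)
class LocalizationResult:
    """Half-open interval of breakpoint positions consistent with a panel."""

    chrom: str
    start: int
    end: int

    @property
    def width(self) -> int:
        return self.end - self.start

    def __contains__(self, bp: int) -> bool:
        return self.start <= bp < self.end


def localize(panel: ProbePanel) -> LocalizationResult:
    """Invert a classified panel into the exact consistent breakpoint set.

    The result is the intersection of all split-probe interiors with
    ``[max proximal end, min distal start]``; a contradiction (empty set)
    signals a mis-scored panel and raises rather than returning an empty
    interval.
    """
    splits = [p for p in panel.probes if panel.classifications[p.name] == SPLIT]
    if not splits:
        raise PanelError("panel has no split probe; breakpoint not localizable")
    lo = max(p.start + 1 for p in splits)
    hi = min(p.end for p in splits)
    for p in panel.probes:
        label = panel.classifications[p.name]
        if label == PROXIMAL:
            lo = max(lo, p.end)
        elif label == DISTAL:
            hi = min(hi, p.start + 1)
    if lo >= hi:
        raise PanelError("contradictory panel: no breakpoint position is consistent")
    return LocalizationResult(panel.chrom, lo, hi)


def simulate_panel(chrom: str, chrom_len: int, bp: int, n_probes: int,
                   rng: np.random.Generator,
                   min_len: int = 1000, max_len: int = 20000) -> ProbePanel:
    """Random probe panel scored against a hidden breakpoint.

    One probe is forced to straddle ``bp`` so the panel is localizable;
    requires ``0 < bp < chrom_len``.
    """
    if not 0 < bp < chrom_len:
        raise PanelError("breakpoint must be strictly inside the chromosome")
    probes = []
    left = int(rng.integers(max(0, bp - max_len + 1), bp))
    right = int(rng.integers(bp + 1, min(chrom_len, bp + max_len) + 1))
    probes.append(Probe("straddle", chrom, left, right))
    for i in range(n_probes - 1):
        length = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(0, max(1, chrom_len - length)))
        probes.append(Probe(f"probe{i}", chrom, start, start + length))
    labels = {p.name: classify_probe(p, bp) for p in probes}
    return ProbePanel(tuple(probes), labels)


def panel_from_tables(probe_bed: pd.DataFrame, labels: pd.DataFrame) -> ProbePanel:
    """Build a panel from a BED-style probe table and a (name, label) table."""
    probes = tuple(Probe(str(r["name"]), str(r["chrom"]), int(r["start"]), int(r["end"]))
                   for _, r in probe_bed.iterrows())
    classifications = {str(r["name"]): str(r["label"]) for _, r in labels.iterrows()}
    return ProbePanel(probes, classifications)


def read_probe_bed(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "name"], comment="#")


def read_labels(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=r"\s+", header=None, names=["name", "label"],
                       comment="#")


def write_interval_bed(result: LocalizationResult, path, name: str = "breakpoint") -> None:
    with open(path, "w") as fh:
        fh.write(f"{result.chrom}\t{result.start}\t{result.end}\t{name}\n")
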