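"""Repeat-family composition of candidates versus genomic background.

The screen asks whether candidate SINEUPs prefer particular SINE subtypes.
The statistic is the Pearson correlation between the family-frequency
vector of candidate-embedded repeats and the frequency vector of all
genomic copies, aligned over the union of families with zero imputation.
A correlation near 1 means the candidates simply mirror the genomic
abundance of each family — no enrichment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from sineup_scan.errors import SineupError
from sineup_scan.models import RepeatFeature


@dataclass
class EnrichmentResult:
    families: list[str]
    freq_candidates: np.ndarray
    freq_genome: np.ndarray
    pearson_r: float
    fold_per_family: np.ndarray
    undefined_r: bool = False

    def to_frame(
        self,
        n_cand: Mapping[str, int] | None = None,
        n_genome: Mapping[str, int] | None = None,
    ) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "family": self.families,
                "freq_cand": self.freq_candidates,
                "freq_genome": self.freq_genome,
                "fold": self.fold_per_family,
            }
        )
        if n_cand is not None:
            frame.insert(1, "n_cand", [n_cand.get(f, 0) for f in self.families])
        if n_genome is not None:
            frame.insert(
                2 if n_cand is not None else 1,
                "n_genome",
                [n_genome.get(f, 0) for f in self.families],
            )
        return frame


def family_frequencies(
    repeats: Iterable[RepeatFeature], key: str = "name"
) -> pd.Series:
    """Copy-number-weighted frequency of each repeat identity.

    ``key`` selects the grouping level: "name" distinguishes SINE subtypes
    (FRAM vs AluY vs MIRb), "family" aggregates (Alu, MIR), "class" is the
    coarsest level. Frequencies sum to 1; an empty input is an error.
    """
    attr = {"name": "repeat_name", "family": "repeat_family", "class": "repeat_class"}
    if key not in attr:
        raise ValueError(f"key must be one of {sorted(attr)}, got {key!r}")
    labels = [getattr(r, attr[key]) for r in repeats]
    if not labels:
        raise SineupError("cannot compute frequencies of an empty repeat set")
    counts = pd.Series(labels, dtype="object").value_counts().sort_index()
    return counts / counts.sum()


def enrichment_correlation(
    cand: Mapping[str, float] | pd.Series, genome: Mapping[str, float] | pd.Series
) -> EnrichmentResult:
    """Pearson correlation between two family-frequency tables.

    Tables are aligned over the union of their families; a family absent
    from one side gets frequency 0. With fewer than two families the
    correlation is undefined (error); a zero-variance vector flags
    ``undefined_r`` (r = nan) instead of crashing. Per-family fold change is
    candidate/genome, with 0/0 yielding nan.
    """
    cand = pd.Series(cand, dtype=float)
    genome = pd.Series(genome, dtype=float)
    families = sorted(set(cand.index) | set(genome.index))
    if len(families) < 2:
        raise SineupError(
            f"correlation needs >=2 families, got {len(families)}"
        )
    fc = cand.reindex(families, fill_value=0.0).to_numpy()
    fg = genome.reindex(families, fill_value=0.0).to_numpy()
    undefined = bool(np.ptp(fc) == 0 or np.ptp(fg) == 0)
    if undefined:
        r = math.nan
    else:
        r = float(stats.pearsonr(fc, fg).statistic)
    # x/0 -> inf (present only in candidates), 0/0 -> nan (undefined)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.divide(fc, fg)
    return EnrichmentResult(
        families=list(families),
        freq_candidates=fc,
        freq_genome=fg,
        pearson_r=r,
        fold_per_family=fold,
        undefined_r=undefined,
    )


def candidate_repeat_features(candidates: Sequence) -> list[RepeatFeature]:
    """Distinct embedded repeat copies across a candidate list.

    A repeat copy shared by several (antisense, sense) rows of the same
    antisense transcript is counted once.
    """
    seen: dict[tuple, RepeatFeature] = {}
    for c in candidates:
        for r in c.embedded_repeats:
            seen.setdefault(
                (r.chrom, r.interval.start, r.interval.end, r.repeat_name), r
            )
    return list(seen.values())
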