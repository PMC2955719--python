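"""Per-region conservation summaries and family-level pattern classification.

For each region class the all-vs-all pair scores are condensed into an
integer-rounded average and a (min, max) range.  A family is then classified
by comparing per-region averages against two thresholds:

* ``inverted`` — every conserved-class region (promoter, 5'-UTR, SPCR,
  intron, 3'-UTR) averages at or above ``conserved_thresh`` while the MPCR
  averages at or below ``diversified_thresh``.  This is the
  super-diversification regime in which the mature-protein coding region is
  the *least* conserved part of the gene.
* ``conventional`` — the usual situation: coding conserved, some noncoding
  region diversified.
* ``uniform`` — everything conserved.
* ``mixed`` — anything else.

Default thresholds (80/60) sit in the empirical gap between conserved-region
score averages and diversified-MPCR averages for this score scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .gene_models import FamilySet, RegionKind
from .pairwise_scoring import (
    AlignParams,
    RegionScoreMatrix,
    ScoringError,
    all_vs_all,
)

#: region classes expected to be conserved under the inverted pattern
CONSERVED_CLASS = (
    RegionKind.PROMOTER,
    RegionKind.UTR5,
    RegionKind.SPCR,
    RegionKind.INTRON,
    RegionKind.UTR3,
)

#: noncoding region classes (used by the conventional-pattern rule)
NONCODING_CLASS = (
    RegionKind.PROMOTER,
    RegionKind.UTR5,
    RegionKind.INTRON,
    RegionKind.UTR3,
)


class ProfileError(ValueError):
    """Raised for profiles that cannot be computed or classified."""


def _round_half_up(x: float) -> int:
    import math
    return math.floor(x + 0.5)


def summarize_region(matrix: RegionScoreMatrix) -> tuple[int, tuple[int, int]]:
    """Average (sum of pair scores / number of pairs, rounded) and range."""
    off = matrix.offdiag_scores()
    if off.size == 0:
        raise ProfileError("score matrix has no off-diagonal pairs")
    avg = _round_half_up(float(off.sum()) / off.size)
    return avg, (int(off.min()), int(off.max()))


@dataclass
class RegionSummary:
    average: int
    range: tuple[int, int]
    n_pairs: int
    n_members: int


@dataclass
class ConservationProfile:
    family_id: str
    regions: dict[RegionKind, RegionSummary] = field(default_factory=dict)
    matrices: dict[RegionKind, RegionScoreMatrix] = field(default_factory=dict)
    method: str = "ktuple"
    pattern: str | None = None
    contrast: float | None = None
    conserved_thresh: int = 80
    diversified_thresh: int = 60

    def averages(self) -> dict[RegionKind, int]:
        return {k: s.average for k, s in self.regions.items()}


def classify_pattern(
    averages: dict[RegionKind, int] | ConservationProfile,
    conserved_thresh: int = 80,
    diversified_thresh: int = 60,
) -> str:
    """Classify a family's per-region score averages into a pattern.

    ``inverted`` requires all conserved-class averages >= ``conserved_thresh``
    and the MPCR average <= ``diversified_thresh``; ``conventional`` requires
    the MPCR average >= ``conserved_thresh`` with some noncoding average
    <= ``diversified_thresh``; ``uniform`` requires every average >=
    ``conserved_thresh``; anything else is ``mixed``.
    """
    if isinstance(averages, ConservationProfile):
        averages = averages.averages()
    averages = {RegionKind(k): v for k, v in averages.items()}
    if RegionKind.MPCR not in averages:
        raise ProfileError("classification requires an MPCR average")
    conserved = [v for k, v in averages.items() if k in CONSERVED_CLASS]
    if len(conserved) < 2:
        raise ProfileError("classification requires >=2 conserved-class regions")
    mpcr = averages[RegionKind.MPCR]
    noncoding = [v for k, v in averages.items() if k in NONCODING_CLASS]
    if all(v >= conserved_thresh for v in conserved) and mpcr <= diversified_thresh:
        return "inverted"
    if mpcr >= conserved_thresh and any(v <= diversified_thresh for v in noncoding):
        return "conventional"
    if all(v >= conserved_thresh for v in averages.values()):
        return "uniform"
    return "mixed"


def profile_family(
    family: FamilySet,
    method: str = "ktuple",
    params: AlignParams | None = None,
    k: int = 2,
    band: int = 5,
    conserved_thresh: int = 80,
    diversified_thresh: int = 60,
) -> ConservationProfile:
    """Score every shared region all-vs-all and classify the family pattern.

    Regions annotated in fewer than two members are skipped with a warning.
    ``contrast`` is the mean of conserved-class region averages minus the
    MPCR average — positive values indicate the inverted regime.
    """
    profile = ConservationProfile(
        family.family_id,
        method=method,
        conserved_thresh=conserved_thresh,
        diversified_thresh=diversified_thresh,
    )
    for kind in RegionKind:
        if kind == RegionKind.INTERGENIC:
            continue
        seqs = family.region_seqs(kind)
        if len(seqs) == 0:
            continue
        if len(seqs) < 2:
            warnings.warn(
                f"region {kind.value} present in fewer than 2 members; skipped"
            )
            continue
        try:
            mat = all_vs_all(seqs, method=method, params=params, k=k, band=band,
                             region_kind=kind.value)
        except ScoringError as exc:
            raise ProfileError(f"region {kind.value}: {exc}") from exc
        avg, rng = summarize_region(mat)
        profile.matrices[kind] = mat
        profile.regions[kind] = RegionSummary(
            avg, rng, len(mat.pairs), mat.n
        )
    averages = profile.averages()
    profile.pattern = classify_pattern(
        averages, conserved_thresh, diversified_thresh
    )
    conserved = [v for kk, v in averages.items() if kk in CONSERVED_CLASS]
    profile.contrast = (
        sum(conserved) / len(conserved) - averages[RegionKind.MPCR]
    )
    return profile


def profile_table(profile: ConservationProfile) -> "pandas.DataFrame":
    """Tabular view of a profile (region, n_pairs, average, min, max)."""
    import pandas as pd

    rows = []
    for kind, s in profile.regions.items():
        rows.append(
            {
                "family": profile.family_id,
                "region": kind.value,
                "n_members": s.n_members,
                "n_pairs": s.n_pairs,
                "average": s.average,
                "min": s.range[0],
                "max": s.range[1],
            }
        )
    return pd.DataFrame(rows)
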