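"""Simulator of tandem gene-array evolution under gene conversion and selection.

The generative model behind the "inverted conservation" pattern: an ancestral
gene unit (flanking intergenic DNA, promoter, 5'-UTR, SPCR, intron, MPCR,
3'-UTR) is duplicated into a tandem array and evolved for a fixed number of
generations under three forces:

* **point mutation** — an origin-fixation scheme in which the per-site
  substitution rate is the neutral rate ``mu`` scaled by a region-specific
  acceptance weight: ``omega_mpcr`` for nonsynonymous MPCR changes (>1 means
  diversifying selection), 1 for synonymous MPCR changes, and
  ``accept_conserved`` (<1 means purifying selection) for all other gene
  regions; intergenic flanks are neutral.  Changes that create an internal
  stop codon or destroy the terminal stop are always rejected.
* **gene conversion** — per generation each copy is converted with
  probability ``gamma`` from a uniformly chosen donor copy; the tract start
  falls in the intergenic/terminal flanks with probability ``init_bias``
  (uniform along the unit otherwise), extends in a random direction with
  geometric length (mean ``tract_mean``), and overwrites the homologous
  recipient segment.  Conversions that disrupt the recipient's open reading
  frame are rejected.
* **array geometry** — copies are stored in sense orientation; the first
  copy is written to the output array reverse-complemented (an inverted
  repeat) but compared in sense orientation like the rest.

Every proposed event is logged, and replaying the log from the ancestral
array reproduces the final sequences bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .codon_evolution import GENETIC_CODE, ng86_pair
from .conservation_profile import ConservationProfile, profile_family
from .gene_models import (
    FamilySet,
    GeneModel,
    Region,
    RegionKind,
)
from .region_phylogeny import DiscordanceResult, region_discordance

_BASES = ("A", "C", "G", "T")
_STOPS = {"TAA", "TAG", "TGA"}


class SimulationError(ValueError):
    """Raised for invalid simulation parameters or malformed event logs."""


DEFAULT_REGION_LENGTHS = {
    "promoter": 200,
    "utr5": 58,
    "spcr": 57,
    "intron": 100,
    "mpcr": 300,
    "utr3": 200,
    "intergenic": 400,
}


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters; defaults describe a seven-member array whose
    MPCR is under strong diversifying selection while the rest of the gene is
    under purifying selection and recurrent intergenically-initiated
    conversion."""

    n_copies: int = 7
    region_lengths: dict = field(default_factory=lambda: dict(DEFAULT_REGION_LENGTHS))
    generations: int = 1500
    mu: float = 3e-5
    gamma: float = 0.005
    tract_mean: float = 300.0
    init_bias: float = 0.8
    omega_mpcr: float = 10.0
    accept_conserved: float = 0.1
    inverted_first: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_copies < 2:
            raise SimulationError("n_copies must be >= 2")
        if self.generations < 0:
            raise SimulationError("generations must be >= 0")
        for name in ("mu", "gamma", "init_bias", "accept_conserved"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {v}")
        if self.omega_mpcr <= 0:
            raise SimulationError("omega_mpcr must be > 0")
        if self.tract_mean < 1:
            raise SimulationError("tract_mean must be >= 1")
        lens = self.region_lengths
        missing = set(DEFAULT_REGION_LENGTHS) - set(lens)
        if missing:
            raise SimulationError(f"region_lengths missing {sorted(missing)}")
        if (lens["spcr"] + lens["mpcr"]) % 3:
            raise SimulationError("spcr + mpcr length must be a multiple of 3")


class _Layout:
    """Coordinates of one gene unit: flank5 | gene regions | flank3."""

    def __init__(self, lens: dict):
        self.flank5 = lens["intergenic"] // 2
        self.flank3 = lens["intergenic"] - self.flank5
        pos = self.flank5
        self.regions: dict[str, tuple[int, int]] = {}
        for name in ("promoter", "utr5", "spcr", "intron", "mpcr", "utr3"):
            self.regions[name] = (pos, pos + lens[name])
            pos += lens[name]
        self.gene_end = pos
        self.unit_len = pos + self.flank3
        self.spcr = self.regions["spcr"]
        self.mpcr = self.regions["mpcr"]
        self.spcr_len = lens["spcr"]
        self.coding_len = lens["spcr"] + lens["mpcr"]
        self.n_codons = self.coding_len // 3

    def region_of(self, pos: int) -> str:
        if pos < self.flank5 or pos >= self.gene_end:
            return "intergenic"
        for name, (s, e) in self.regions.items():
            if s <= pos < e:
                return name
        raise AssertionError("unreachable")

    def coding_pos(self, pos: int) -> int | None:
        if self.spcr[0] <= pos < self.spcr[1]:
            return pos - self.spcr[0]
        if self.mpcr[0] <= pos < self.mpcr[1]:
            return self.spcr_len + pos - self.mpcr[0]
        return None

    def unit_pos(self, coding_pos: int) -> int:
        if coding_pos < self.spcr_len:
            return self.spcr[0] + coding_pos
        return self.mpcr[0] + (coding_pos - self.spcr_len)

    def codon(self, unit: list[str], codon_idx: int) -> str:
        return "".join(
            unit[self.unit_pos(codon_idx * 3 + o)] for o in range(3)
        )


def _random_ancestor(layout: _Layout, lens: dict, rng: np.random.Generator) -> str:
    unit = [_BASES[i] for i in rng.integers(0, 4, size=layout.unit_len)]
    # coding region: ATG, sense codons, terminal stop
    sense = sorted(c for c in GENETIC_CODE if GENETIC_CODE[c] != "*")
    codons = ["ATG"]
    for _ in range(layout.n_codons - 2):
        codons.append(sense[rng.integers(0, len(sense))])
    codons.append(sorted(_STOPS)[rng.integers(0, 3)])
    coding = "".join(codons)
    for p, base in enumerate(coding):
        unit[layout.unit_pos(p)] = base
    return "".join(unit)


def _coding_intact(layout: _Layout, unit: list[str]) -> bool:
    """ORF check: no internal stop, terminal stop preserved."""
    for ci in range(layout.n_codons - 1):
        if layout.codon(unit, ci) in _STOPS:
            return False
    return layout.codon(unit, layout.n_codons - 1) in _STOPS


@dataclass
class SimFamily:
    """A simulated tandem array with full ground truth."""

    params: SimParams
    ancestor: str
    copies: list[str]
    events: list[dict]
    layout: _Layout = field(repr=False)

    @property
    def copy_ids(self) -> list[str]:
        return [f"g{i + 1}" for i in range(len(self.copies))]

    def region_seq(self, copy_idx: int, kind: str) -> str:
        s, e = self.layout.regions[kind]
        return self.copies[copy_idx][s:e]

    def to_family(self, family_id: str = "sim") -> FamilySet:
        """FamilySet view with gene models placed on the tandem array."""
        fam = FamilySet(family_id)
        unit_len = self.layout.unit_len
        for i, cid in enumerate(self.copy_ids):
            off = i * unit_len
            inverted = self.params.inverted_first and i == 0
            strand = "-" if inverted else "+"
            regions = []
            seqs: dict[RegionKind, str] = {}
            for name, (s, e) in self.layout.regions.items():
                if inverted:
                    start, end = off + unit_len - e, off + unit_len - s
                else:
                    start, end = off + s, off + e
                regions.append(Region(RegionKind(name), start, end, strand))
                seqs[RegionKind(name)] = self.copies[i][s:e]
            model = GeneModel(cid, "array", regions, strand)
            fam.members[cid] = (model, seqs)
        return fam

    def array_sequence(self) -> str:
        """The parent array: concatenated units, first copy inverted."""
        from Bio.Seq import Seq

        parts = []
        for i, unit in enumerate(self.copies):
            if self.params.inverted_first and i == 0:
                parts.append(str(Seq(unit).reverse_complement()))
            else:
                parts.append(unit)
        return "".join(parts)

    def write(self, fasta_path, gff_path, log_path=None, params_path=None) -> None:
        from .gene_models import write_family

        fam = self.to_family()
        write_family(fam, {"array": self.array_sequence()}, fasta_path, gff_path)
        if log_path is not None:
            import json

            with open(log_path, "w") as fh:
                for ev in self.events:
                    fh.write(json.dumps(ev) + "\n")
        if params_path is not None:
            import json

            with open(params_path, "w") as fh:
                json.dump(asdict(self.params), fh, indent=2)
                fh.write("\n")

    def mpcr_codon_seqs(self) -> dict[str, str]:
        """In-frame MPCR codon subsequences (full codons only) per copy."""
        lay = self.layout
        first_full = (3 - lay.spcr_len % 3) % 3
        n_mpcr = lay.mpcr[1] - lay.mpcr[0]
        usable = ((n_mpcr - first_full) // 3) * 3
        out = {}
        for i, cid in enumerate(self.copy_ids):
            s = lay.mpcr[0] + first_full
            out[cid] = self.copies[i][s:s + usable]
        return out


def simulate(params: SimParams) -> SimFamily:
    """Run the tandem-array simulation; deterministic for a fixed seed."""
    rng = np.random.default_rng(params.seed)
    lens = params.region_lengths
    layout = _Layout(lens)
    ancestor = _random_ancestor(layout, lens, rng)
    copies = [list(ancestor) for _ in range(params.n_copies)]
    events: list[dict] = []

    w_max_mpcr = max(1.0, params.omega_mpcr)
    # per-region proposal intensity: neutral rate x max acceptance weight
    region_rates = []
    for name, (s, e) in layout.regions.items():
        w = w_max_mpcr if name == "mpcr" else params.accept_conserved
        region_rates.append((name, s, e, params.mu * w * (e - s)))
    region_rates.append(("flank5", 0, layout.flank5, params.mu * layout.flank5))
    region_rates.append(
        ("flank3", layout.gene_end, layout.unit_len, params.mu * layout.flank3)
    )

    flank_positions = layout.flank5 + layout.flank3

    for gen in range(params.generations):
        for c in range(params.n_copies):
            unit = copies[c]
            for name, s, e, lam in region_rates:
                if lam <= 0:
                    continue
                for _ in range(rng.poisson(lam)):
                    pos = int(s + rng.integers(0, e - s))
                    old = unit[pos]
                    choices = [b for b in _BASES if b != old]
                    alt = choices[rng.integers(0, 3)]
                    syn = None
                    accept_p = 1.0
                    cp = layout.coding_pos(pos)
                    if cp is not None:
                        ci = cp // 3
                        codon = layout.codon(unit, ci)
                        mutant = (
                            codon[: cp % 3] + alt + codon[cp % 3 + 1:]
                        )
                        terminal = ci == layout.n_codons - 1
                        if (mutant in _STOPS) != terminal:
                            accept_p = 0.0  # premature stop or stop loss
                        else:
                            syn = GENETIC_CODE[codon] == GENETIC_CODE[mutant]
                            if name == "mpcr":
                                w = 1.0 if syn else params.omega_mpcr
                                accept_p = w / w_max_mpcr
                            else:
                                accept_p = 1.0  # proposal rate already scaled
                    accepted = accept_p > 0 and (
                        accept_p >= 1.0 or rng.random() < accept_p
                    )
                    events.append(
                        {
                            "type": "mutation",
                            "gen": gen,
                            "copy": c,
                            "pos": pos,
                            "from": old,
                            "to": alt,
                            "region": name,
                            "syn": syn,
                            "accepted": bool(accepted),
                        }
                    )
                    if accepted:
                        unit[pos] = alt
        # conversion pass (after mutation, fixed copy order)
        if params.gamma > 0:
            for c in range(params.n_copies):
                if rng.random() >= params.gamma:
                    continue
                donor = int(rng.integers(0, params.n_copies - 1))
                if donor >= c:
                    donor += 1
                if rng.random() < params.init_bias:
                    fp = int(rng.integers(0, flank_positions))
                    init = fp if fp < layout.flank5 else layout.gene_end + fp - layout.flank5
                else:
                    init = int(rng.integers(0, layout.unit_len))
                direction = 1 if rng.random() < 0.5 else -1
                length = int(rng.geometric(1.0 / params.tract_mean))
                if direction == 1:
                    start, end = init, min(layout.unit_len, init + length)
                else:
                    start, end = max(0, init - length + 1), init + 1
                recipient = copies[c]
                saved = recipient[start:end]
                recipient[start:end] = copies[donor][start:end]
                ok = _coding_intact(layout, recipient)
                if not ok:
                    recipient[start:end] = saved
                events.append(
                    {
                        "type": "conversion",
                        "gen": gen,
                        "donor": donor,
                        "recipient": c,
                        "start": start,
                        "length": end - start,
                        "drawn_length": length,
                        "direction": direction,
                        "accepted": bool(ok),
                    }
                )

    return SimFamily(
        params=params,
        ancestor=ancestor,
        copies=["".join(u) for u in copies],
        events=events,
        layout=layout,
    )


def replay(events: list[dict], ancestor: str, n_copies: int) -> list[str]:
    """Re-apply an event log to the ancestral array.

    Returns the final copy sequences; applying a SimFamily's own log must
    reproduce its ``copies`` exactly.
    """
    copies = [list(ancestor) for _ in range(n_copies)]
    unit_len = len(ancestor)
    for idx, ev in enumerate(events):
        if not ev.get("accepted", False):
            continue
        if ev["type"] == "mutation":
            pos, c = ev["pos"], ev["copy"]
            if not (0 <= pos < unit_len) or not (0 <= c < n_copies):
                raise SimulationError(f"event {idx}: out-of-bounds mutation")
            copies[c][pos] = ev["to"]
        elif ev["type"] == "conversion":
            s, ln = ev["start"], ev["length"]
            d, r = ev["donor"], ev["recipient"]
            if s < 0 or s + ln > unit_len or not (0 <= d < n_copies):
                raise SimulationError(f"event {idx}: out-of-bounds conversion")
            copies[r][s:s + ln] = copies[d][s:s + ln]
        else:
            raise SimulationError(f"event {idx}: unknown type {ev['type']!r}")
    return ["".join(u) for u in copies]


def divergent_pair_params(seed: int, omega_mpcr: float = 1.0) -> SimParams:
    """Two-copy, conversion-free parameters for dN/dS regime experiments.

    The mutation budget (mu=1e-4 over 1000 generations) diverges the MPCR to
    roughly 80-85% identity — the moderately diverged window in which
    pairwise dN/dS estimation is informative.
    """
    return SimParams(
        n_copies=2,
        seed=seed,
        gamma=0.0,
        omega_mpcr=omega_mpcr,
        accept_conserved=1.0,
        generations=1000,
        mu=1e-4,
        inverted_first=False,
    )


# ---------------------------------------------------------------------------
# ground-truth recovery: run the full analysis pipeline on simulated data
# ---------------------------------------------------------------------------

@dataclass
class RecoveryResult:
    pattern: str
    contrast: float
    mean_omega: float | None
    n_omega_pairs: int
    discordant: bool
    label: str
    profile: ConservationProfile = field(repr=False)
    discordance: DiscordanceResult | None = field(repr=False, default=None)


def mean_mpcr_omega(fam_mpcr: dict[str, str]) -> tuple[float | None, int]:
    """Mean NG86 omega over all MPCR codon-sequence pairs where defined."""
    import itertools

    omegas = []
    ids = list(fam_mpcr)
    for a, b in itertools.combinations(ids, 2):
        stats = ng86_pair(fam_mpcr[a], fam_mpcr[b], n_bootstrap=0)
        if stats.omega is not None:
            omegas.append(stats.omega)
    if not omegas:
        return None, 0
    return float(np.mean(omegas)), len(omegas)


def recover_params(fam: "SimFamily | FamilySet") -> RecoveryResult:
    """Analyze a (simulated) family and classify its evolutionary regime.

    Runs the conservation profile, mean MPCR dN/dS, and region-tree
    discordance; the family is called ``concerted+diversifying`` when the
    profile is inverted, mean omega exceeds one and the region trees
    disagree.  A uniform profile is called ``neutral``.
    """
    if isinstance(fam, SimFamily):
        if len(fam.copies) < 2:
            raise SimulationError("recovery needs >=2 copies")
        family = fam.to_family()
        mpcr = fam.mpcr_codon_seqs()
    else:
        family = fam
        from .gene_models import RegionKind as RK

        spcrs = family.region_seqs(RK.SPCR)
        mpcrs = family.region_seqs(RK.MPCR)
        mpcr = {}
        for gid, mseq in mpcrs.items():
            spcr_len = len(spcrs.get(gid, ""))
            first_full = (3 - spcr_len % 3) % 3
            usable = ((len(mseq) - first_full) // 3) * 3
            mpcr[gid] = mseq[first_full:first_full + usable]

    profile = profile_family(family)
    mean_omega, n_pairs = mean_mpcr_omega(mpcr)
    disc = None
    discordant = False
    if len(family.members) >= 3:
        disc = region_discordance(family)
        discordant = disc.discordant
    if (
        profile.pattern == "inverted"
        and mean_omega is not None
        and mean_omega > 1
        and discordant
    ):
        label = "concerted+diversifying"
    elif profile.pattern == "uniform":
        label = "neutral"
    else:
        label = "other"
    return RecoveryResult(
        pattern=profile.pattern,
        contrast=profile.contrast,
        mean_omega=mean_omega,
        n_omega_pairs=n_pairs,
        discordant=discordant,
        label=label,
        profile=profile,
        discordance=disc,
    )
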