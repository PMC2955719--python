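"""Pairwise dN/dS by Nei-Gojobori (1986) counting and allele substitution tallies.

``ng86_pair`` counts synonymous and nonsynonymous sites with one-third
weighting per codon position, averages multi-hit codon differences over all
minimal mutational pathways, applies the Jukes-Cantor correction
``d = -3/4 ln(1 - 4p/3)`` and reports dN/dS (omega) with codon-bootstrap
standard errors.  Conventions (recorded in output metadata):

* changes *to* a stop codon count as nonsynonymous and sites are not
  renormalised, so N + S = 3 x n_codons exactly;
* pathways passing *through* a stop codon are excluded from averaging unless
  every pathway does;
* codon pairs containing an alignment gap or a stop codon in either sequence
  are excluded from counting.

``tally_alleles`` pools substitutions across the unique cDNAs of an allele
set, deduplicates them by (coding position, alternate base), classifies each
in its codon context, and reports nonsynonymous/synonymous count ratios
separately for the signal-peptide and mature-protein coding regions.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .gene_models import GeneModel, extract_coding


class CodonError(ValueError):
    """Raised for invalid coding-sequence inputs."""


_BASES = "TCAG"
_TABLE = CodonTable.unambiguous_dna_by_id[1]


def _build_code() -> dict[str, str]:
    code = dict(_TABLE.forward_table)
    for stop in _TABLE.stop_codons:
        code[stop] = "*"
    return code


GENETIC_CODE = _build_code()


def _syn_fraction(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon.

    Each position contributes 1/3 site per possible change; changes to stop
    codons are nonsynonymous.
    """
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if GENETIC_CODE[mutant] == aa and GENETIC_CODE[mutant] != "*":
                s += 1.0 / 3.0
    return s, 3.0 - s


# cache: site counts for all 61 sense codons (stops handled by exclusion)
_SITE_CACHE = {
    c: _syn_fraction(c)
    for c in ("".join(t) for t in itertools.product(_BASES, repeat=3))
    if GENETIC_CODE[c] != "*"
}


def _pathway_diffs(ca: str, cb: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences for a codon pair.

    All orderings of the differing positions are enumerated; pathways with a
    stop-codon intermediate are dropped unless every pathway has one.
    """
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = ca
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            aa_cur, aa_nxt = GENETIC_CODE[cur], GENETIC_CODE[nxt]
            if aa_nxt == "*" and pos != order[-1]:
                through_stop = True
            if aa_cur == aa_nxt and aa_nxt != "*":
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        paths.append((through_stop, sd, nd))
    usable = [(sd, nd) for stop, sd, nd in paths if not stop]
    if not usable:
        usable = [(sd, nd) for _, sd, nd in paths]
    sd = sum(p[0] for p in usable) / len(usable)
    nd = sum(p[1] for p in usable) / len(usable)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC-corrected distance; NaN (flagged by callers) when p >= 3/4."""
    if p < 0:
        raise CodonError("proportion must be non-negative")
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class SubstStats:
    """Nei-Gojobori substitution statistics for one coding pair."""

    n_codons: int
    Nd: float
    Sd: float
    N: float
    S: float
    pN: float
    pS: float
    dN: float
    dS: float
    se_dN: float | None = None
    se_dS: float | None = None
    omega: float | None = None
    undefined_reason: str | None = None
    # per-codon tallies kept for bootstrap and oracles
    per_codon: dict[str, np.ndarray] | None = field(default=None, repr=False)
    meta: dict = field(default_factory=lambda: {
        "stop_mutations": "nonsynonymous, no site renormalisation",
        "stop_pathways": "excluded unless all pathways pass through a stop",
        "gapped_or_stop_codon_pairs": "excluded",
    }, repr=False)


def _split_codons(seq: str) -> list[str]:
    return [seq[i:i + 3] for i in range(0, len(seq), 3)]


def ng86_pair(
    a: str,
    b: str,
    n_bootstrap: int = 1000,
    seed: int | None = None,
) -> SubstStats:
    """Nei-Gojobori dN/dS for an aligned in-frame coding pair.

    Sequences must be equal length and a multiple of 3; ``-`` gaps are
    permitted but gapped codon pairs are excluded from counting.  Bootstrap
    SEs resample codons; pass ``n_bootstrap=0`` to skip them.
    """
    a, b = a.upper(), b.upper()
    if len(a) != len(b):
        raise CodonError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) % 3:
        raise CodonError(f"length {len(a)} not a multiple of 3")
    if not a:
        raise CodonError("empty sequences")
    Ni, Si, Ndi, Sdi = [], [], [], []
    for ca, cb in zip(_split_codons(a), _split_codons(b)):
        if "-" in ca or "-" in cb:
            continue
        if ca not in _SITE_CACHE or cb not in _SITE_CACHE:
            if GENETIC_CODE.get(ca) == "*" or GENETIC_CODE.get(cb) == "*":
                continue  # stop codon pair: excluded
            raise CodonError(f"invalid codon pair {ca}/{cb}")
        sa, na = _SITE_CACHE[ca]
        sb, nb = _SITE_CACHE[cb]
        sd, nd = _pathway_diffs(ca, cb)
        Si.append((sa + sb) / 2.0)
        Ni.append((na + nb) / 2.0)
        Sdi.append(sd)
        Ndi.append(nd)
    n_codons = len(Si)
    if n_codons == 0:
        raise CodonError("no ungapped sense codon pairs to compare")
    Ni, Si = np.array(Ni), np.array(Si)
    Ndi, Sdi = np.array(Ndi), np.array(Sdi)
    N, S = float(Ni.sum()), float(Si.sum())
    Nd, Sd = float(Ndi.sum()), float(Sdi.sum())
    pN, pS = Nd / N, Sd / S
    dN, dS = jukes_cantor(pN), jukes_cantor(pS)
    reason = None
    if math.isnan(dN) or math.isnan(dS):
        reason = "proportion >= 3/4: Jukes-Cantor correction undefined"
    omega = None
    if reason is None:
        if dS > 0:
            omega = dN / dS
        else:
            reason = "dS = 0: omega undefined"
    se_dN = se_dS = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n_codons, size=(n_bootstrap, n_codons))
        with np.errstate(invalid="ignore", divide="ignore"):
            pn_b = Ndi[idx].sum(axis=1) / Ni[idx].sum(axis=1)
            ps_b = Sdi[idx].sum(axis=1) / Si[idx].sum(axis=1)
            dn_b = np.where(pn_b < 0.75, -0.75 * np.log(1 - 4 * pn_b / 3), np.nan)
            ds_b = np.where(ps_b < 0.75, -0.75 * np.log(1 - 4 * ps_b / 3), np.nan)
        se_dN = float(np.nanstd(dn_b, ddof=1))
        se_dS = float(np.nanstd(ds_b, ddof=1))
    return SubstStats(
        n_codons=n_codons, Nd=Nd, Sd=Sd, N=N, S=S, pN=pN, pS=pS,
        dN=dN, dS=dS, se_dN=se_dN, se_dS=se_dS, omega=omega,
        undefined_reason=reason,
        per_codon={"N": Ni, "S": Si, "Nd": Ndi, "Sd": Sdi},
    )


# ---------------------------------------------------------------------------
# codon-aware alignment
# ---------------------------------------------------------------------------

def _translate_checked(seq: str, name: str) -> str:
    if len(seq) % 3:
        raise CodonError(f"{name}: length {len(seq)} not a multiple of 3")
    protein = str(Seq(seq).translate())
    internal = protein[:-1].find("*")
    if internal != -1:
        raise CodonError(f"{name}: internal stop codon at codon {internal + 1}")
    return protein


def codon_align(a: str, b: str) -> tuple[str, str]:
    """Codon-aware pairwise alignment: align proteins, thread back codons.

    Returns nucleotide alignments whose gaps are in multiples of 3.  Terminal
    stop codons are stripped before alignment and re-appended afterwards.
    """
    a, b = a.upper(), b.upper()
    pa, pb = _translate_checked(a, "a"), _translate_checked(b, "b")
    stop_a = pa.endswith("*")
    stop_b = pb.endswith("*")
    core_a = a[:-3] if stop_a else a
    core_b = b[:-3] if stop_b else b
    prot_a = pa[:-1] if stop_a else pa
    prot_b = pb[:-1] if stop_b else pb

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    aln = aligner.align(prot_a, prot_b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])

    codons_a = _split_codons(core_a)
    codons_b = _split_codons(core_b)
    out_a, out_b = [], []
    ia = ib = 0
    for ca, cb in zip(row_a, row_b):
        if ca == "-":
            out_a.append("---")
        else:
            out_a.append(codons_a[ia])
            ia += 1
        if cb == "-":
            out_b.append("---")
        else:
            out_b.append(codons_b[ib])
            ib += 1
    if stop_a or stop_b:
        out_a.append(a[-3:] if stop_a else "---")
        out_b.append(b[-3:] if stop_b else "---")
    return "".join(out_a), "".join(out_b)


# ---------------------------------------------------------------------------
# allele tallies
# ---------------------------------------------------------------------------

def ratio(nonsyn: int, syn: int) -> float | None:
    """Nonsyn/syn count ratio rounded half-up to 2 decimals; None if syn = 0."""
    if nonsyn < 0 or syn < 0:
        raise CodonError("substitution counts must be non-negative")
    if syn == 0:
        return None
    q = Decimal(nonsyn) / Decimal(syn)
    return float(q.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class AlleleTally:
    """Pooled substitution tallies for one gene's allele set."""

    gene_id: str
    n_total: int
    n_unique_cdna: int
    n_unique_protein: int
    n_excluded: int
    regions: dict[str, dict]  # region -> {nonsyn, syn, ratio}


def _classify_sub(ref_codon: str, pos_in_codon: int, alt: str) -> str:
    """Classify a single substitution in its reference codon context."""
    mutant = ref_codon[:pos_in_codon] + alt + ref_codon[pos_in_codon + 1:]
    aa_ref = GENETIC_CODE.get(ref_codon)
    aa_mut = GENETIC_CODE.get(mutant)
    if aa_ref is None or aa_mut is None:
        return "nonsyn"
    if aa_ref == aa_mut and aa_mut != "*":
        return "syn"
    return "nonsyn"


def tally_alleles(
    ref_model: GeneModel,
    parent_seq: str,
    alleles: dict[str, str] | list[str],
) -> AlleleTally:
    """Pool and classify substitutions across an allele set.

    Exact duplicate cDNAs are collapsed first; every distinct (position,
    alternate base) substitution observed among the unique alleles is counted
    once and classified synonymous/nonsynonymous against the reference codon
    carrying only that change.  Substitutions are assigned to SPCR or MPCR by
    nucleotide position (a split boundary codon belongs to the SPCR).
    Alleles whose length differs from the reference by a non-multiple of 3
    are excluded with a warning and counted in the report.
    """
    if isinstance(alleles, list):
        alleles = {f"allele_{i}": s for i, s in enumerate(alleles)}
    spcr, mpcr, _ = extract_coding(ref_model, parent_seq)
    coding = spcr + mpcr
    spcr_len = len(spcr)

    n_total = len(alleles)
    unique: dict[str, str] = {}
    n_excluded = 0
    for name, seq in alleles.items():
        seq = seq.upper()
        if abs(len(seq) - len(coding)) % 3:
            warnings.warn(f"allele {name}: frameshift-length difference; excluded")
            n_excluded += 1
            continue
        unique.setdefault(seq, name)
    unique_seqs = list(unique)
    proteins = set()
    subs: set[tuple[int, str]] = set()  # (coding position, alternate base)
    for seq in unique_seqs:
        if len(seq) == len(coding):
            aligned_ref, aligned_alt = coding, seq
        else:
            aligned_ref, aligned_alt = codon_align(coding, seq)
        proteins.add(str(Seq(seq).translate()))
        ref_pos = -1
        for r, q in zip(aligned_ref, aligned_alt):
            if r != "-":
                ref_pos += 1
            if r == "-" or q == "-":
                continue
            if r != q:
                subs.add((ref_pos, q))

    counts = {
        "spcr": {"nonsyn": 0, "syn": 0},
        "mpcr": {"nonsyn": 0, "syn": 0},
    }
    for pos, alt in subs:
        codon_idx = pos // 3
        ref_codon = coding[codon_idx * 3:codon_idx * 3 + 3]
        cls = _classify_sub(ref_codon, pos % 3, alt)
        region = "spcr" if pos < spcr_len else "mpcr"
        counts[region][cls] += 1

    regions = {}
    for region, c in counts.items():
        regions[region] = {
            "nonsyn": c["nonsyn"],
            "syn": c["syn"],
            "ratio": ratio(c["nonsyn"], c["syn"]),
        }
    return AlleleTally(
        gene_id=ref_model.gene_id,
        n_total=n_total,
        n_unique_cdna=len(unique_seqs),
        n_unique_protein=len(proteins),
        n_excluded=n_excluded,
        regions=regions,
    )
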