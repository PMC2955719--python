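"""Simulator integrity: determinism, replay, conversion and selection regimes."""

import itertools

import numpy as np
import pytest
from scipy.stats import mannwhitneyu, spearmanr

from tandemfam import (
    SimParams,
    divergent_pair_params,
    profile_family,
    read_family,
    recover_params,
    replay,
    simulate,
)
from tandemfam.concerted_sim import SimulationError
from tandemfam.gene_models import RegionKind


def test_invalid_parameters_rejected_before_simulation():
    with pytest.raises(SimulationError):
        SimParams(n_copies=1)
    with pytest.raises(SimulationError):
        SimParams(mu=1.5)
    with pytest.raises(SimulationError):
        SimParams(omega_mpcr=0)
    with pytest.raises(SimulationError):
        SimParams(tract_mean=0.5)
    with pytest.raises(SimulationError):
        SimParams(region_lengths={**SimParams().region_lengths, "spcr": 58})


def test_no_mutation_no_conversion_keeps_copies_ancestral():
    fam = simulate(SimParams(mu=0.0, gamma=0.0, generations=200, seed=1))
    assert all(c == fam.ancestor for c in fam.copies)


def test_fixed_seed_is_byte_identical():
    p = SimParams(seed=42, generations=400)
    f1, f2 = simulate(p), simulate(p)
    assert f1.copies == f2.copies
    assert f1.events == f2.events
    assert f1.ancestor == f2.ancestor


def test_event_log_replay_reproduces_final_sequences():
    fam = simulate(SimParams(seed=7, generations=600, gamma=0.02))
    replayed = replay(fam.events, fam.ancestor, len(fam.copies))
    assert replayed == fam.copies


def test_replay_rejects_out_of_bounds_events():
    fam = simulate(SimParams(seed=1, generations=50))
    bad = [{"type": "mutation", "copy": 0, "pos": 10**6, "to": "A",
            "accepted": True}]
    with pytest.raises(SimulationError, match="event 0"):
        replay(bad, fam.ancestor, len(fam.copies))
    bad = [{"type": "conversion", "donor": 0, "recipient": 1, "start": -5,
            "length": 10, "accepted": True}]
    with pytest.raises(SimulationError, match="event 0"):
        replay(bad, fam.ancestor, len(fam.copies))


def test_conversion_tracts_copy_donor_content_and_stay_in_bounds():
    fam = simulate(SimParams(seed=9, generations=800, gamma=0.05))
    unit_len = fam.layout.unit_len
    conv = [e for e in fam.events if e["type"] == "conversion"]
    assert conv, "expected conversion events at gamma=0.05"
    # step through the log; after each accepted conversion the recipient
    # tract must equal the donor tract at that moment
    copies = [list(fam.ancestor) for _ in fam.copies]
    for ev in fam.events:
        if not ev["accepted"]:
            continue
        if ev["type"] == "mutation":
            copies[ev["copy"]][ev["pos"]] = ev["to"]
        else:
            s, ln = ev["start"], ev["length"]
            assert 0 <= s and s + ln <= unit_len
            copies[ev["recipient"]][s:s + ln] = copies[ev["donor"]][s:s + ln]
            assert copies[ev["recipient"]][s:s + ln] == \
                copies[ev["donor"]][s:s + ln]
    assert ["".join(c) for c in copies] == fam.copies


def test_tract_length_mean_matches_parameter():
    drawn = []
    seed = 0
    while len(drawn) < 500:
        fam = simulate(SimParams(seed=1000 + seed, generations=300,
                                 gamma=0.5, mu=0.0))
        drawn += [e["drawn_length"] for e in fam.events
                  if e["type"] == "conversion"]
        seed += 1
    mean = np.mean(drawn[:max(500, len(drawn))])
    assert abs(mean - 300) / 300 < 0.15


def test_substitution_density_scales_linearly_with_mu():
    """At gamma=0 divergence grows ~ 2*mu*generations (within 20%)."""
    gens = 200
    mus = [5e-5, 1e-4, 2e-4]
    obs = []
    for mu in mus:
        ps = []
        for rep in range(4):
            p = SimParams(n_copies=2, seed=500 + rep, gamma=0.0, mu=mu,
                          generations=gens, omega_mpcr=1.0,
                          accept_conserved=1.0, inverted_first=False)
            fam = simulate(p)
            a, b = fam.copies
            diffs = sum(x != y for x, y in zip(a, b))
            ps.append(diffs / len(a))
        obs.append(np.mean(ps))
    slope = np.polyfit(mus, obs, 1)[0]
    expected = 2 * gens
    assert abs(slope - expected) / expected < 0.20


def test_conversion_raises_noncoding_similarity():
    """gamma=0.05 vs gamma=0: conversion homogenizes noncoding regions."""
    def noncoding_scores(gamma, seed0):
        out = []
        for rep in range(12):
            p = SimParams(seed=seed0 + rep, n_copies=4, generations=500,
                          mu=1e-4, gamma=gamma, omega_mpcr=1.0,
                          accept_conserved=1.0)
            prof = profile_family(simulate(p).to_family())
            vals = [prof.regions[k].average for k in
                    (RegionKind.PROMOTER, RegionKind.INTRON, RegionKind.UTR3)]
            out.append(np.mean(vals))
        return out

    with_conv = noncoding_scores(0.05, 100)
    without = noncoding_scores(0.0, 200)
    assert np.mean(with_conv) > np.mean(without)
    assert mannwhitneyu(with_conv, without, alternative="greater").pvalue < 0.05


def test_contrast_increases_with_conversion_rate():
    """Conservation contrast tracks the conversion rate (Spearman > 0.8).

    The sweep runs where the differential is well-posed: the MPCR under
    strong diversifying selection regenerates its diversity much faster than
    conversion can erase it, while the flanking regions are mutation-limited,
    so rising conversion rates homogenize the conserved class preferentially.
    """
    gammas = [0.0, 0.005, 0.01, 0.02, 0.04]
    contrasts = []
    for g in gammas:
        vals = []
        for rep in range(5):
            p = SimParams(seed=700 + rep, n_copies=5, generations=600,
                          mu=4e-4, gamma=g, omega_mpcr=30.0,
                          accept_conserved=1.0)
            prof = profile_family(simulate(p).to_family())
            vals.append(prof.contrast)
        contrasts.append(np.mean(vals))
    rho = spearmanr(gammas, contrasts).statistic
    assert rho > 0.8


def test_recovery_classifies_regimes(tmp_path):
    labels = [recover_params(simulate(SimParams(seed=s))).label
              for s in range(5)]
    assert labels.count("concerted+diversifying") >= 4
    labels = [recover_params(simulate(
        SimParams(seed=50 + s, gamma=0.0, omega_mpcr=1.0,
                  accept_conserved=1.0))).label for s in range(5)]
    assert labels.count("neutral") >= 4


def test_divergent_pair_regimes_shift_omega():
    from tandemfam.codon_evolution import ng86_pair

    pos, neut = [], []
    for s in range(15):
        f = simulate(divergent_pair_params(s, omega_mpcr=5.0))
        a, b = f.mpcr_codon_seqs().values()
        st = ng86_pair(a, b, n_bootstrap=0)
        if st.omega is not None:
            pos.append(st.omega)
        f = simulate(divergent_pair_params(100 + s, omega_mpcr=1.0))
        a, b = f.mpcr_codon_seqs().values()
        st = ng86_pair(a, b, n_bootstrap=0)
        if st.omega is not None:
            neut.append(st.omega)
    assert np.mean(pos) > np.mean(neut)
    assert np.mean([w > 1 for w in pos]) >= 0.9


def test_written_family_roundtrips_through_fasta_gff(tmp_path):
    """The array FASTA+GFF3 reload to the simulator's own region sequences,
    including the reverse-complemented inverted first copy."""
    fam = simulate(SimParams(seed=11, generations=300))
    fa, gff = tmp_path / "sim.fa", tmp_path / "sim.gff3"
    fam.write(fa, gff)
    loaded = read_family(fa, gff)
    assert set(loaded.members) == set(fam.copy_ids)
    for i, cid in enumerate(fam.copy_ids):
        _, seqs = loaded.members[cid]
        for kind in ("promoter", "utr5", "spcr", "intron", "mpcr", "utr3"):
            assert seqs[RegionKind(kind)] == fam.region_seq(i, kind), \
                (cid, kind)


def test_single_copy_family_rejected():
    with pytest.raises(SimulationError):
        SimParams(n_copies=1)
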