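"""Reference evaluation scenarios with planted ground truth.

Each builder sets up one of the package's standard recovery experiments at
its study conditions (community sizes, divergences, planted effect sizes)
and measures how well the corresponding stage recovers the planted truth.
They are used by the test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import binning, epili, exprnorm, simcom, stimresp, taxgroup

CONDS = list(simcom.DEFAULT_DESIGN.condition_ids)


# ---------------------------------------------------------------------------
# Binning recovery: 6 genomes, pairwise GC gaps >= 0.10, distinct coverage
# profiles, ~500 contigs.
# ---------------------------------------------------------------------------

def binning_recovery(seed: int) -> Dict[str, float]:
    rng = np.random.default_rng(seed)
    gcs = [0.24, 0.34, 0.44, 0.54, 0.64, 0.74]
    specs = [
        simcom.GenomeSpec(f"g{i + 1}", length=420_000, gc_target=gc,
                          n_orfs=20, n_marker_genes=5)
        for i, gc in enumerate(gcs)
    ]
    depths = {
        s.name: {c: float(rng.uniform(5, 80)) for c in CONDS} for s in specs
    }
    com = simcom.build_community(specs, depths, mean_contig_len=5000,
                                 seed=int(rng.integers(2 ** 31)))
    feats = binning.compute_features(com.contig_seqs, com.contig_dna_counts,
                                     CONDS)
    asg = binning.cluster_bins(feats)
    asg = binning.refine_bins_tnf(asg, feats)
    asg = binning.rescue_by_linkage(asg, com.linkage)
    truth = com.truth["contig_to_genome"]
    big = feats[feats["length"] >= 2000]["contig_id"]
    ari = adjusted_rand_score([truth[c] for c in big],
                              [asg.labels[c] for c in big])
    return {"ari": float(ari), "n_contigs": int(len(feats)),
            "n_contigs_2kb": int(len(big)), "n_bins": len(asg.bins)}


# ---------------------------------------------------------------------------
# OCS correctness: strain family at {1, 2, 5, 10}% divergence plus an
# unrelated genome from a different compositional model.
# ---------------------------------------------------------------------------

def ocs_correctness(seed: int) -> Dict[str, object]:
    rng = np.random.default_rng(seed)
    base = simcom.build_genome(
        simcom.GenomeSpec("base", length=100_000, gc_target=0.55, n_orfs=8),
        seed=int(rng.integers(2 ** 31)))
    other = simcom.build_genome(
        simcom.GenomeSpec("other", length=100_000, gc_target=0.55, n_orfs=8),
        seed=int(rng.integers(2 ** 31)))
    divergences = (0.01, 0.02, 0.05, 0.10)
    strains = {
        d: simcom.derive_strain(base, d, seed=int(rng.integers(2 ** 31)))
        for d in divergences
    }
    ani_dev = {}
    mean_ani = {}
    for d, strain in strains.items():
        oracle = 100.0 * simcom.pairwise_identity(base.seq, strain.seq)
        res = taxgroup.anib("base", base.seq, "s", strain.seq)
        ani_dev[d] = abs(res.mean_ani - oracle)
        mean_ani[d] = res.mean_ani
    seqs = {"base": base.seq, "s02": strains[0.02].seq,
            "s10": strains[0.10].seq, "other": other.seq}
    _, _, groups = taxgroup.pairwise_ocs(seqs)
    by_bin = {m: g.ocs_id for g in groups for m in g.members}
    return {
        "mean_ani": mean_ani,
        "ani_oracle_abs_dev": ani_dev,
        "strain2_same_ocs": by_bin["base"] == by_bin["s02"],
        "strain10_separate_ocs": by_bin["base"] != by_bin["s10"],
        "other_model_separate_ocs": by_bin["base"] != by_bin["other"],
    }


# ---------------------------------------------------------------------------
# Responsive-gene recovery: 50 planted responders (fold 8) among 5000 genes.
# ---------------------------------------------------------------------------

def responsive_recovery(seed: int, noise: str = "poisson",
                        n_genes: int = 5000, n_resp: int = 50,
                        fold: float = 8.0, baseline_mean: float = 200.0,
                        ) -> Dict[str, float]:
    orfs = pd.DataFrame({
        "orf_id": [f"o{i:05d}" for i in range(n_genes)],
        "genome": "g1", "length": 999,
        "base_expr": baseline_mean * simcom.READ_LEN / 999,
    })
    resp_ids = list(orfs["orf_id"][:n_resp])
    plan = {
        oid: ("AcPro", "positive" if i % 2 == 0 else "negative", fold)
        for i, oid in enumerate(resp_ids)
    }
    depths = {"g1": {c: 30.0 for c in CONDS}}
    dna, mrna = simcom.simulate_counts(orfs, simcom.DEFAULT_DESIGN, depths,
                                       plan, noise=noise, seed=seed)
    expr = exprnorm.expression_table(dna, mrna, CONDS)
    calls = stimresp.responsive_genes(expr, simcom.DEFAULT_DESIGN)
    hits = calls[(calls.stimulus == "AcPro") & (calls.direction != "none")]
    called = set(hits["orf_id"])
    truth = set(resp_ids)
    tp = len(called & truth)
    fp = len(called - truth)
    dirs = dict(zip(hits["orf_id"], hits["direction"]))
    direction_ok = sum(
        1 for i, oid in enumerate(resp_ids)
        if dirs.get(oid) == ("positive" if i % 2 == 0 else "negative"))
    return {
        "sensitivity": tp / n_resp,
        "false_positive_rate": fp / (n_genes - n_resp),
        "direction_accuracy": direction_ok / n_resp,
    }


# ---------------------------------------------------------------------------
# Arrow-midpoint partitioning: genes planted to respond under exactly one
# of SucEET / SucOC / AcProEET.
# ---------------------------------------------------------------------------

def partition_recovery(seed: int, n_genes: int = 300,
                       effect: float = 10.0) -> Dict[str, float]:
    rng = np.random.default_rng(seed)
    design = simcom.DEFAULT_DESIGN
    variables = list(design.variable_map)
    labels = rng.choice(variables, size=n_genes)
    X = pd.DataFrame(
        {v: [1.0 if c in conds else 0.0 for c in CONDS]
         for v, conds in design.variable_map.items()}, index=CONDS)
    base = rng.uniform(50, 200, size=n_genes)
    Y = np.outer(base, np.ones(5))
    for i, lab in enumerate(labels):
        for j, c in enumerate(CONDS):
            if c in design.variable_map[lab]:
                Y[i, j] *= effect
    Y = pd.DataFrame(rng.poisson(Y).astype(float), columns=CONDS,
                     index=[f"gene{i}" for i in range(n_genes)])
    ordination = stimresp.wcca(Y, X)
    part = stimresp.partition_by_arrow_midpoints(ordination)
    assigned = part.notna()
    accuracy = float((part[assigned].to_numpy() == labels[assigned]).mean())
    return {"accuracy": accuracy,
            "assigned_fraction": float(assigned.mean())}


# ---------------------------------------------------------------------------
# Pilin pipeline: synthetic pilins with planted truth, incl. indel cases.
# ---------------------------------------------------------------------------

def pilin_truth_agreement(seed: int, n_pilins: int = 100) -> Dict[str, float]:
    rng = np.random.default_rng(seed)
    n_ok = 0
    fields = ("cleavage_index", "mature_length", "aromatic_count",
              "aromatic_pct", "essential_hits")
    for i in range(n_pilins):
        n_ess = int(rng.integers(0, 8))
        plan = simcom.PilinPlan(
            leader_length=int(rng.integers(15, 30)),
            mature_length=int(rng.integers(57, 120)),
            aromatic_count=int(rng.integers(max(n_ess, 1), 14)),
            essential_flags=tuple(j < n_ess for j in range(7)),
            insertion=(40, int(rng.integers(1, 5))) if i % 5 == 0 else None,
        )
        protein, truth = simcom._pilin_protein(
            plan, np.random.default_rng(int(rng.integers(2 ** 31))))
        ann = epili.annotate_pilin(f"p{i}", protein, simcom.REFERENCE_PILIN,
                                   simcom.ESSENTIAL_POSITIONS)
        expected_call = epili.call_conductivity(truth["aromatic_pct"],
                                                truth["essential_hits"])
        ok = all(getattr(ann, f) == truth[f] for f in fields)
        ok = ok and ann.conductivity_call == expected_call
        ok = ok and ann.pilin_type == truth["type"]
        n_ok += ok
    return {"agreement": n_ok / n_pilins, "n_pilins": n_pilins}
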