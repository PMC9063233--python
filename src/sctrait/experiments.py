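"""Seeded validation experiments for the statistical layer.

Each function runs a self-contained simulation study against the package's
own synthetic generators and returns summary numbers: agreement of the
sampled rotation null with exact enumeration, type-I calibration and power
of the enrichment grid, recovery of true cycling fractions, trajectory
classification accuracy, and pseudocell convergence.  They are what
``scripts/acceptance.py`` reports and what the acceptance-level tests
assert; problem sizes are documented in the methods note.

All randomness derives from the single ``seed`` argument via SeedSequence
substreams, so every experiment is exactly reproducible.
"""

from __future__ import annotations

import numpy as np

from .cellstate import classify_proliferating, classify_trajectory, cycle_index, cycle_score, module_score, normalize, pseudocell_aggregate
from .enrichment import empirical_p, null_distribution, run_grid, t_sum
from .mapping import GeneSetCatalog
from .synthetic import GwasSimConfig, ScSimConfig, default_panels, generate_gwas, generate_sc

__all__ = [
    "oracle_agreement",
    "grid_calibration",
    "power_curve",
    "cycle_recovery",
    "trajectory_classification",
    "pseudocell_convergence",
]


def _child_seed(*keys: int) -> int:
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % 2**31)


def oracle_agreement(
    seed: int = 0, n_instances: int = 100, n_perm: int = 10_000
) -> dict:
    """Sampled rotation-null p versus the exactly enumerated null.

    For random genomes with up to 2,000 markers and random marker sets, the
    sampled empirical p (``n_perm`` draws) is compared with the exact
    enumeration over all m-1 rotations; agreement means
    ``|p_sampled - p_exact| <= 2*sqrt(p(1-p)/n_perm) + 1/n_perm``.
    """
    rng = np.random.default_rng(seed)
    n_ok = 0
    for _ in range(n_instances):
        m = int(rng.integers(200, 2001))
        b = rng.standard_normal(m)
        idx = np.sort(rng.choice(m, size=int(rng.integers(10, 101)), replace=False))
        t = t_sum(b, idx)
        exact, _ = null_distribution(b, idx, enumerate_all=True)
        p_exact, _ = empirical_p(t, exact)
        sampled, _ = null_distribution(
            b, idx, n_perm=n_perm, seed=int(rng.integers(2**31)), enumerate_all=False
        )
        p_sampled, _ = empirical_p(t, sampled)
        tol = 2 * np.sqrt(p_exact * (1 - p_exact) / n_perm) + 1 / n_perm
        n_ok += abs(p_sampled - p_exact) <= tol
    return {"agreement_rate": n_ok / n_instances, "n": n_instances}


def _replicate_grid(seed: int, enrichment_lambda: float, n_traits: int, n_sets: int,
                    n_perm: int = 10_000):
    """One trait x set grid on a fresh simulated genome.

    With ``enrichment_lambda > 1`` the first trait is enriched in set00.
    """
    cfg = GwasSimConfig(seed=_child_seed(seed, 0), enrichment_lambda=enrichment_lambda)
    base = generate_gwas(cfg, n_sets=n_sets, trait_id="trait00")
    enriched = None
    if enrichment_lambda > 1:
        enriched = GeneSetCatalog({"set00": base.catalog.sets["set00"]})
    traits = [
        generate_gwas(
            GwasSimConfig(seed=_child_seed(seed, 1 + t),
                          enrichment_lambda=enrichment_lambda),
            enriched if t == 0 else None,
            annotation=base.annotation, catalog=base.catalog,
            trait_id=f"trait{t:02d}",
        ).effects
        for t in range(n_traits)
    ]
    return run_grid(traits, base.catalog, base.annotation,
                    n_perm=n_perm, seed=_child_seed(seed, 99))


def grid_calibration(
    seed: int = 0, n_replicates: int = 200, n_traits: int = 5, n_sets: int = 8,
    alpha: float = 0.05,
) -> dict:
    """Type-I error and p-value uniformity of the null enrichment grid."""
    from scipy import stats

    ps = []
    for rep in range(n_replicates):
        grid = _replicate_grid(_child_seed(seed, 300, rep), 1.0, n_traits, n_sets)
        ps.extend(grid.loc[grid["reason"] == "", "p_emp"].tolist())
    ps = np.asarray(ps)
    return {
        "type_i_error": float((ps <= alpha).mean()),
        "ks_uniform_pvalue": float(stats.kstest(ps, "uniform").pvalue),
        "n": len(ps),
    }


def power_curve(
    seed: int = 0, lambdas: tuple = (1.0, 2.0, 3.0), n_replicates: int = 50,
    n_traits: int = 3, n_sets: int = 8,
) -> dict:
    """Mean -log10(p) of the enriched cell across SD-inflation levels.

    Also reports how often the lambda = 3 enriched cell attains the
    grid-wide smallest FDR q.
    """
    out: dict = {"n": n_replicates}
    for lam in lambdas:
        neglog, top = [], 0
        for rep in range(n_replicates):
            grid = _replicate_grid(_child_seed(seed, 400, rep, int(lam * 10)),
                                   lam, n_traits, n_sets)
            cell = grid[(grid["trait_id"] == "trait00") & (grid["set_id"] == "set00")]
            neglog.append(-np.log10(cell["p_emp"].iloc[0]))
            top += bool(cell["q_fdr"].iloc[0] <= grid["q_fdr"].min() + 1e-12)
        out[f"mean_neglog10_p_lambda{lam:g}"] = float(np.mean(neglog))
        if lam == max(lambdas):
            out["top_hit_rate"] = top / n_replicates
    return out


def cycle_recovery(
    seed: int = 0, n_replicates: int = 20, fractions: tuple = (0.1, 0.3, 0.5),
    n_cells_per_cluster: int = 2000, cycle_effect: float = 5.0, n_genes: int = 300,
) -> dict:
    """Recovery of true cycling fractions by the proliferation classifier.

    One cluster per true fraction; a replicate succeeds when every recovered
    cycle index is within 0.05 of its truth and the cycling-flag balanced
    accuracy is at least 0.9.
    """
    clusters = {f"frac{int(100 * f):02d}": f for f in fractions}
    ok = 0
    errs, bas = [], []
    for rep in range(n_replicates):
        cfg = ScSimConfig(
            seed=_child_seed(seed, 500, rep), n_genes=n_genes,
            n_cells_per_group=n_cells_per_cluster,
            cluster_labels=list(clusters), timepoint_labels=["Control"],
            cycling_fraction_per_cluster=clusters, cycle_effect=cycle_effect,
            module_trajectories={},
        )
        cyc, _ = default_panels(n_genes, module_ids=(), module_size=0)
        sim = generate_sc(cfg, cyc, [])
        norm = normalize(sim.adata)
        flags, _ = classify_proliferating(
            cycle_score(norm, cyc), norm.obs["cluster"]
        )
        idx = cycle_index(flags, norm.obs["cluster"])
        err = max(abs(idx[cl] - f) for cl, f in clusters.items())
        truth = norm.obs["true_cycling"].to_numpy()
        hit = flags.to_numpy()
        tpr = (hit & truth).sum() / truth.sum()
        tnr = (~hit & ~truth).sum() / (~truth).sum()
        ba = 0.5 * (tpr + tnr)
        errs.append(err)
        bas.append(ba)
        ok += (err <= 0.05) and (ba >= 0.9)
    return {
        "success_rate": ok / n_replicates,
        "max_index_error_mean": float(np.mean(errs)),
        "balanced_accuracy_mean": float(np.mean(bas)),
        "n": n_replicates,
    }


def trajectory_classification(seed: int = 0, n_replicates: int = 100) -> dict:
    """Classification of injected peaked versus sustained module shapes.

    Uses the generator defaults: the core antiviral and peaked inflammatory
    modules rise to an interior maximum and return to baseline (peaked);
    the sustained inflammatory module rises and holds (sustained).
    """
    expected = {
        "core_antiviral": "peaked",
        "peaked_inflammatory": "peaked",
        "sustained_inflammatory": "sustained",
    }
    n_ok = 0
    for rep in range(n_replicates):
        cfg = ScSimConfig(
            seed=_child_seed(seed, 600, rep), n_cells_per_group=150,
            cluster_labels=["monocytes"], cycling_fraction_per_cluster={},
        )
        cyc, mods = default_panels(cfg.n_genes)
        norm = normalize(generate_sc(cfg, cyc, mods).adata)
        ms = module_score(norm, mods, group_key="timepoint")
        labels = {m: classify_trajectory(ms.loc[m].to_numpy()) for m in ms.index}
        n_ok += labels == expected
    return {"accuracy": n_ok / n_replicates, "n": n_replicates}


def pseudocell_convergence(seed: int = 0, n_draws: int = 500) -> dict:
    """Exactness and convergence of pseudocell averages.

    A 100-cell cluster sampled at size 100 must reproduce the cluster mean
    exactly; over ``n_draws`` pseudocells from a large cluster, the grand
    mean converges to the cluster mean (max per-gene relative error).
    """
    import anndata as ad
    import pandas as pd

    rng = np.random.default_rng(seed)

    def _cluster(n):
        counts = rng.poisson(4, size=(n, 30)).astype(float) + 1
        obs = pd.DataFrame({"cluster": ["k"] * n},
                           index=[f"c{i}" for i in range(n)])
        return normalize(ad.AnnData(X=counts, obs=obs))

    small = _cluster(100)
    pcs = pseudocell_aggregate(small, size=100, n_pseudocells=3, seed=_child_seed(seed, 700))
    exact_err = float(np.abs(np.asarray(pcs.X) - np.asarray(small.X).mean(axis=0)).max())

    big = _cluster(2000)
    pcs = pseudocell_aggregate(big, size=100, n_pseudocells=n_draws,
                               seed=_child_seed(seed, 701))
    truth = np.asarray(big.X).mean(axis=0)
    rel = np.abs(np.asarray(pcs.X).mean(axis=0) - truth) / truth
    return {
        "exact_max_abs_error": exact_err,
        "grand_mean_max_rel_error": float(rel.max()),
        "n": n_draws,
    }
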