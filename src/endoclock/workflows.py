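"""High-level run functions tying the stages into reproducible analyses.

This package is used from Python, so these functions *are* the command
surface: each one validates its inputs, runs the corresponding stage, writes
its artifacts (trace TSV, summary TSV, annotated NEXUS tree, sweep tables)
into an output directory together with a JSON run manifest (seed, settings,
config hash) sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import CalibrationSet, check_consistency
from .clock import ClockConfig
from .diagnostics import (DatingProblem, apply_scheme, composite_posterior,
                          infinite_sites_regression, root_sweep)
from .host_asr import (HostCharacterMatrix, default_rate_prior,
                       log_bayes_factor, run_asr_mcmc)
from .sampler import MCMCSettings, run_mcmc, two_chain_check
from .treedata import TimeTree, write_annotated_tree

__all__ = ["simulate_to_dir", "date_analysis", "sweep_analysis",
           "composite_analysis", "asr_analysis", "write_manifest"]


def _config_hash(payload: dict) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(outdir: Path, stage: str, seed: int, payload: dict) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "seed": seed,
        "endoclock_version": __version__,
        "config_hash": _config_hash(payload),
        "config": payload,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path


def simulate_to_dir(spec, outdir) -> dict:
    """Generate a scenario dataset and write every pipeline input to disk:
    Newick topology, calibration TSV, partition files, and a truth JSON
    (true ages/rates/hyperparameters for recovery scoring)."""
    from .calibration import save_calibrations_tsv
    from .likelihood import save_partitions
    from .synthetic_data import simulate_dataset

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(spec)
    (outdir / "tree.nwk").write_text(ds.tree.newick() + "\n")
    save_calibrations_tsv(ds.calibrations, outdir / "calibrations.tsv")
    save_partitions(ds.partitions, outdir / "partitions")
    truth = {
        "true_ages": {int(i): float(ds.true_ages[i])
                      for i in ds.tree.internal_ids},
        "true_branch_rates": [float(r)
                              for r in ds.true_rates.branch_rates],
        "true_mu": float(ds.true_mu),
        "true_sigma2": float(ds.true_sigma2),
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    write_manifest(outdir, "simulate", spec.seed, {
        "n_symbiont": spec.n_symbiont, "n_host": spec.n_host,
        "root_age": spec.root_age, "placement": spec.placement,
        "noise_cv": spec.noise_cv, "clock_model": spec.clock.model,
    })
    return {"dataset": ds, "outdir": outdir}


def _summary_frame(summaries) -> pd.DataFrame:
    rows = [
        {"node_id": s.node_id, "mean_age": s.mean, "hpd_lower": s.hpd_lower,
         "hpd_upper": s.hpd_upper, "hpd_width": s.hpd_width}
        for s in summaries.values()
    ]
    return pd.DataFrame(rows).sort_values("node_id")


def date_analysis(tree: TimeTree, calibrations: CalibrationSet,
                  clock: ClockConfig, partitions, settings: MCMCSettings,
                  outdir, scheme: str = "best",
                  check_two_chains: bool = False,
                  convergence_tol: float = 0.05) -> dict:
    """One dating run: MCMC, summaries, annotated tree, manifest.

    Returns a dict with the trace, summaries and infinite-sites fit.  With
    ``check_two_chains`` a second chain (seed+1) is run and compared;
    disagreement raises ``RuntimeError``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for note in check_consistency(calibrations, tree):
        print(f"[date] calibration warning: {note}")
    problem = apply_scheme(scheme, DatingProblem(
        tree=tree, calibrations=calibrations, clock=clock,
        partitions=list(partitions) if partitions else [],
    ))
    trace = run_mcmc(problem.tree, problem.calibrations, problem.clock,
                     problem.partitions or None, settings)
    if check_two_chains:
        from dataclasses import replace
        trace_b = run_mcmc(problem.tree, problem.calibrations, problem.clock,
                           problem.partitions or None,
                           replace(settings, seed=settings.seed + 1))
        report = two_chain_check(trace, trace_b, tol=convergence_tol)
        if not report.passed:
            raise RuntimeError(
                f"two-chain convergence check failed: {report.failed[:5]}"
            )
    summaries = trace.summaries()
    trace.to_tsv(outdir / "trace.tsv")
    _summary_frame(summaries).to_csv(outdir / "summary.tsv", sep="\t",
                                     index=False, float_format="%.6g")
    nexus = write_annotated_tree(
        tree, {i: (s.mean, s.hpd_lower, s.hpd_upper)
               for i, s in summaries.items()})
    (outdir / "dated_tree.nex").write_text(nexus)
    slope, intercept, r2 = infinite_sites_regression(summaries)
    write_manifest(outdir, "date", settings.seed, {
        "scheme": scheme, "settings": asdict(settings),
        "clock_model": clock.model, "n_leaves": tree.n_leaves,
        "n_calibrations": len(calibrations),
        "prior_only": settings.prior_only,
    })
    return {"trace": trace, "summaries": summaries,
            "infinite_sites": {"slope": slope, "intercept": intercept,
                               "r2": r2}}


def sweep_analysis(tree, calibrations, grid, clock, partitions, settings,
                   outdir, clade_nodes=None, **kw) -> dict:
    """Root-maximum sweep with its result table and manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = root_sweep(tree, calibrations, grid, clock, partitions,
                        settings, clade_nodes=clade_nodes, **kw)
    df = pd.DataFrame(result.mean_ages,
                      columns=[f"node_{i}" for i in result.clade_nodes])
    df.insert(0, "root_max", result.grid)
    df.to_csv(outdir / "sweep.tsv", sep="\t", index=False,
              float_format="%.6g")
    pd.DataFrame({"node_id": result.clade_nodes,
                  "slope": result.slopes}).to_csv(
        outdir / "sweep_slopes.tsv", sep="\t", index=False,
        float_format="%.6g")
    write_manifest(outdir, "sweep", settings.seed, {
        "grid": list(map(float, result.grid)),
        "settings": asdict(settings), "clock_model": clock.model,
    })
    return {"result": result}


def composite_analysis(tree, calibrations, clock, partitions, settings,
                       outdir, schemes=("best", "Phan", "Max-1", "Max-2",
                                        "SinglePartition", "IR"),
                       node_ids=None) -> dict:
    """Date under several schemes and pool the posteriors.

    The default scheme list is the best-practiced analysis plus the five
    standard alternates, pooled with equal weight.
    """
    from dataclasses import replace

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = DatingProblem(tree=tree, calibrations=calibrations, clock=clock,
                         partitions=list(partitions))
    traces = []
    for k, name in enumerate(schemes):
        problem = apply_scheme(name, base)
        traces.append(run_mcmc(problem.tree, problem.calibrations,
                               problem.clock, problem.partitions,
                               replace(settings, seed=settings.seed + k)))
    summaries = composite_posterior(traces, node_ids=node_ids,
                                    rng=np.random.default_rng(settings.seed))
    _summary_frame(summaries).to_csv(outdir / "composite_summary.tsv",
                                     sep="\t", index=False,
                                     float_format="%.6g")
    write_manifest(outdir, "composite", settings.seed, {
        "schemes": list(schemes), "settings": asdict(settings),
    })
    return {"traces": traces, "summaries": summaries}


def _asr_nexus(tree: TimeTree, marginals) -> str:
    """NEXUS tree with posterior state probabilities as node comments."""
    from .treedata import _quote_label

    el = tree.edge_lengths
    if el is None:
        el = tree.edge_lengths_from_ages()

    def fmt(i: int) -> str:
        if tree.is_leaf(i):
            s = _quote_label(tree.labels[i])
        else:
            s = "(" + ",".join(fmt(c) for c in tree.children[i]) + ")"
            s += (f"[&p_animal={marginals[i, 0]:.6g},"
                  f"p_protist={marginals[i, 1]:.6g}]")
        if i != tree.root:
            s += f":{el[i]:.10g}"
        return s

    return ("#NEXUS\nBEGIN TREES;\n"
            f"    TREE asr = [&R] {fmt(tree.root)};\nEND;\n")


def asr_analysis(tree: TimeTree, chars: HostCharacterMatrix, outdir,
                 seed: int = 0, n_samples: int = 2000, K: int = 32,
                 compute_bf: bool = True) -> dict:
    """Host-lifestyle reconstruction: rate posterior, node marginals, logBF."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = run_asr_mcmc(tree, chars, seed=seed, n_samples=n_samples)
    pd.DataFrame({"q_AP": result.q_ap, "q_PA": result.q_pa,
                  "log_lik": result.log_lik}).to_csv(
        outdir / "rates_trace.tsv", sep="\t", index=False,
        float_format="%.6g")
    marg = result.marginals
    pd.DataFrame({
        "node_id": np.arange(tree.n_nodes),
        "p_animal": marg[:, 0], "p_protist": marg[:, 1],
    }).to_csv(outdir / "node_marginals.tsv", sep="\t", index=False,
              float_format="%.6g")
    (outdir / "asr_tree.nex").write_text(_asr_nexus(tree, marg))
    logbf = None
    if compute_bf:
        logbf = log_bayes_factor(tree, chars, K=K, seed=seed)
    write_manifest(outdir, "asr", seed, {
        "n_samples": n_samples, "K": K,
        "prior_mean": default_rate_prior(tree).mean,
    })
    return {"result": result, "logBF": logbf}
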