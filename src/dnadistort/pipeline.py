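"""End-to-end orchestration: simulate inputs, run every analysis arm,
write a consolidated, reproducible report bundle.

Arms (each optional, at least one enabled):

* trajectory arm: ``.ser`` files per sequence -> equilibration discard,
  terminal-level trim, per-level median/IQR summaries -> MFA over the 17
  parameter groups;
* geometry arm: adducted/control H-bond geometry -> quality-index
  medians and Mann-Whitney comparison;
* mutation arm: mutation table -> per-site counts -> binomial hotspot
  calls, plus 96-channel signatures, smoker-minus-nonsmoker differences
  and the probability-vs-difference correlation.

Outputs are TSV/JSON under the output directory together with a
``manifest.json`` recording inputs, seed and parameter choices; rerunning
with the same config and seed reproduces every file byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import hbond_quality, hotspot_stats, mfa, signature_builder, trajectory_stats
from . import io_formats, synthetic_data

log = logging.getLogger("dnadistort")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """An analysis stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Either point the arms at existing inputs (``ser_dirs``,
    ``geometry_pairs``, ``mutation_table``, ``counts_table``) or set
    ``simulate=True`` to synthesize all of them from ``seed`` first.
    ``hotspots_from_panel`` runs the hotspot arm on the packaged TP53
    panel counts (M=421 substitutions, S=353 candidate guanines).
    """

    out_dir: str | Path = "dnadistort_out"
    seed: int = 0
    simulate: bool = False
    sim_t_total: float = 1000.0
    sim_n_frames_geometry: int = 500
    discard_ps: float = 300.0
    trim_levels: int = 1
    alpha: float = 0.05
    hotspot_mode: str = "point"
    n_candidate_sites: int = 353
    ser_dirs: dict[str, str | Path] = field(default_factory=dict)
    geometry_pairs: dict[str, tuple[str | Path, str | Path]] = field(default_factory=dict)
    mutation_table: str | Path | None = None
    counts_table: str | Path | None = None
    hotspots_from_panel: bool = False

    def any_arm(self) -> bool:
        return bool(
            self.simulate
            or self.ser_dirs
            or self.geometry_pairs
            or self.mutation_table
            or self.counts_table
            or self.hotspots_from_panel
        )


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("[%s] start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


@_stage("simulate")
def _simulate_inputs(config: RunConfig, out: Path, manifest: dict) -> None:
    panel = io_formats.load_fixture_panel()
    inputs = out / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    rng_seed = config.seed
    # Helical trajectories: one directory per sequence x {adducted, control}.
    for i, fx in enumerate(panel):
        for adducted in (True, False):
            tag = f"codon{fx.codon}{'S' if adducted else 'C'}"
            tcfg = synthetic_data.TrajectorySimConfig(
                t_total=config.sim_t_total,
                seed=rng_seed + 13 * i + (1 if adducted else 0),
            )
            series = synthetic_data.gen_helical_trajectory(tcfg, adducted=adducted)
            d = inputs / "ser" / tag
            d.mkdir(parents=True, exist_ok=True)
            for name, s in series.items():
                io_formats.write_ser(s, d / f"{name}.ser")
            config.ser_dirs[tag] = d
    # Bond geometry: adducted pair perturbed, control near-ideal.
    for i, fx in enumerate(panel):
        adducted = synthetic_data.gen_bond_geometry(
            distance_shift=0.15, angle_shift=-12.0,
            distance_sd=0.08, angle_sd=6.0,
            n_frames=config.sim_n_frames_geometry,
            seed=rng_seed + 1000 + i, label=f"codon{fx.codon}S",
        )
        control = synthetic_data.gen_bond_geometry(
            distance_sd=0.08, angle_sd=6.0,
            n_frames=config.sim_n_frames_geometry,
            seed=rng_seed + 2000 + i, label=f"codon{fx.codon}C",
        )
        pa = inputs / f"geometry_codon{fx.codon}_adducted.tsv"
        pc = inputs / f"geometry_codon{fx.codon}_control.tsv"
        io_formats.write_geometry(adducted, pa)
        io_formats.write_geometry(control, pc)
        config.geometry_pairs[f"codon{fx.codon}"] = (pa, pc)
    # Mutation table with the five hotspot-like sites enriched 20x.
    keys = synthetic_data.MutationSimConfig().site_keys()
    mcfg = synthetic_data.MutationSimConfig(
        enriched={keys[i]: 20.0 for i in range(5)}, seed=rng_seed + 5000
    )
    records = synthetic_data.gen_mutation_table(mcfg)
    mut_path = inputs / "mutations.tsv"
    io_formats.write_mutation_table(records, mut_path)
    config.mutation_table = mut_path
    manifest["simulated"] = {
        "sequences": [fx.codon for fx in panel],
        "n_sequences": len(panel),
        "parameters_per_sequence": len(io_formats.PARAMETER_NAMES),
        "t_total_ps": config.sim_t_total,
        "mutation_sites": mcfg.n_sites,
        "mutation_total": mcfg.m_total,
        "enriched_sites": sorted(mcfg.enriched),
    }


@_stage("trajstats")
def _run_trajectory_arm(config: RunConfig, out: Path, manifest: dict) -> pd.DataFrame:
    rows = []
    for seq_name, d in sorted(config.ser_dirs.items()):
        d = Path(d)
        for ser_path in sorted(d.glob("*.ser")):
            series = io_formats.read_ser(ser_path)
            series = trajectory_stats.discard_equilibration(series, config.discard_ps)
            series = trajectory_stats.trim_terminal_levels(series, config.trim_levels)
            for summ in trajectory_stats.level_summaries(series):
                rows.append(
                    {
                        "sequence": seq_name,
                        "parameter": summ.parameter_name,
                        "level": summ.level,
                        "median": summ.median,
                        "q1": summ.q1,
                        "q3": summ.q3,
                        "n_frames": summ.n_frames,
                    }
                )
    df = pd.DataFrame(rows)
    df.to_csv(out / "summaries.tsv", sep="\t", index=False)
    manifest["trajectory"] = {
        "n_sequences": df["sequence"].nunique(),
        "parameters": sorted(df["parameter"].unique()),
        "discard_ps": config.discard_ps,
        "trim_levels": config.trim_levels,
        "post_trim_widths": {
            p: int(g["level"].nunique()) for p, g in df.groupby("parameter")
        },
    }
    return df


@_stage("mfa")
def _run_mfa_arm(summaries: pd.DataFrame, out: Path, manifest: dict) -> None:
    groups = mfa.groups_from_summaries(summaries)
    model = mfa.mfa_fit(groups)
    pct = mfa.percent_variance(model)
    scores = pd.DataFrame(
        model.scores,
        index=pd.Index(model.obs_names, name="sequence"),
        columns=[f"PC{k + 1}" for k in range(model.n_components)],
    )
    scores.to_csv(out / "mfa_scores.tsv", sep="\t")
    corr = mfa.variable_correlations(model, 0)
    corr.per_variable.to_csv(out / "mfa_varcorr_pc1.tsv", sep="\t", index=False)
    payload = {
        "groups": list(model.group_names),
        "first_eigenvalues": model.first_eigenvalues.tolist(),
        "eigenvalues": model.eigenvalues.tolist(),
        "percent_variance": pct.tolist(),
        "group_contributions_pc1": model.group_contributions[:, 0].tolist(),
    }
    (out / "mfa_model.json").write_text(json.dumps(payload, indent=1))
    manifest["mfa"] = {
        "n_groups": len(model.group_names),
        "percent_variance_pc1": pct[0],
        "percent_variance_pc2": pct[1] if pct.size > 1 else None,
    }


@_stage("ih")
def _run_geometry_arm(config: RunConfig, out: Path, manifest: dict) -> None:
    rows = []
    for label, (path_a, path_c) in sorted(config.geometry_pairs.items()):
        ga = io_formats.read_geometry(path_a)
        gc = io_formats.read_geometry(path_c)
        ra = hbond_quality.ih_series(ga)
        rc = hbond_quality.ih_series(gc)
        cmp = hbond_quality.compare_ih(ra.values, rc.values)
        rows.append(
            {
                "sequence": label,
                "median_adducted": ra.median,
                "iqr_adducted": ra.iqr,
                "median_control": rc.median,
                "iqr_control": rc.iqr,
                "median_difference": cmp.median_difference,
                "absolute_difference": cmp.absolute_difference,
                "mannwhitney_p": cmp.p_value,
            }
        )
    pd.DataFrame(rows).to_csv(out / "ih.tsv", sep="\t", index=False)
    manifest["ih"] = {"n_pairs": len(rows)}


@_stage("hotspots")
def _run_hotspot_arm(config: RunConfig, out: Path, manifest: dict) -> None:
    counts: list[hotspot_stats.SiteMutationCount] = []
    if config.hotspots_from_panel:
        panel = io_formats.load_fixture_panel()
        M, S = 421, 353
        counts = [
            hotspot_stats.SiteMutationCount(f"codon{fx.codon}", fx.observed_gt, M, S)
            for fx in panel
        ]
    elif config.counts_table is not None:
        df = pd.read_csv(config.counts_table, sep="\t")
        counts = [
            hotspot_stats.SiteMutationCount(str(r.site_key), int(r.N), int(r.M), int(r.S))
            for r in df.itertuples(index=False)
        ]
    elif config.mutation_table is not None:
        records, _ = io_formats.read_mutation_table(config.mutation_table)
        per_site = pd.Series([r.site_key for r in records]).value_counts()
        M = len(records)
        S = config.n_candidate_sites
        counts = [
            hotspot_stats.SiteMutationCount(str(k), int(n), M, S)
            for k, n in per_site.items()
        ]
    calls = hotspot_stats.classify_hotspots(counts, alpha=config.alpha,
                                            mode=config.hotspot_mode)
    df = pd.DataFrame(
        {
            "site_key": [c.site_key for c in calls],
            "N": [c.N for c in calls],
            "p_value": [f"{c.p_value:.6g}" for c in calls],
            "threshold": [f"{c.threshold:.6g}" for c in calls],
            "is_hotspot": [c.is_hotspot for c in calls],
        }
    )
    df.to_csv(out / "hotspots.tsv", sep="\t", index=False)
    manifest["hotspots"] = {
        "mode": config.hotspot_mode,
        "alpha": config.alpha,
        "n_sites_tested": len(calls),
        "n_hotspots": int(sum(c.is_hotspot for c in calls)),
        "hotspot_sites": [c.site_key for c in calls if c.is_hotspot],
    }


@_stage("signatures")
def _run_signature_arm(config: RunConfig, out: Path, manifest: dict) -> None:
    records, n_rejected = io_formats.read_mutation_table(config.mutation_table)
    strata = {r.stratum for r in records}
    sigs = {}
    for stratum in sorted(strata & {"smoker", "nonsmoker"}):
        sig = signature_builder.build_signature(records, stratum)
        sigs[stratum] = sig
        pd.DataFrame(
            {
                "context": [ch.pyr_context for ch in signature_builder.CHANNELS],
                "substitution": [ch.substitution for ch in signature_builder.CHANNELS],
                "count": sig.counts,
                "probability_pct": sig.probabilities,
            }
        ).to_csv(out / f"signature_{stratum}.tsv", sep="\t", index=False)
    manifest["signatures"] = {"strata": sorted(sigs), "rejected_rows": n_rejected}
    if {"smoker", "nonsmoker"} <= set(sigs):
        diff = signature_builder.signature_difference(sigs["smoker"], sigs["nonsmoker"])
        pd.DataFrame(
            {
                "context": [ch.pyr_context for ch in signature_builder.CHANNELS],
                "substitution": [ch.substitution for ch in signature_builder.CHANNELS],
                "difference_pct": diff,
            }
        ).to_csv(out / "signature_difference.tsv", sep="\t", index=False)
        try:
            r, p = signature_builder.probability_vs_difference_correlation(
                sigs["smoker"], sigs["nonsmoker"], "C>A"
            )
            payload = {"substitution": "C>A", "r": r, "p": p, "n_contexts": 16}
        except ValueError as exc:
            payload = {"substitution": "C>A", "error": str(exc)}
        (out / "signature_correlation.json").write_text(json.dumps(payload, indent=1))
        manifest["signatures"]["correlation"] = payload


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled arms and return the manifest (also written).

    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    if not config.any_arm():
        raise ValueError("no pipeline arm enabled")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "discard_ps": config.discard_ps,
            "trim_levels": config.trim_levels,
            "alpha": config.alpha,
            "hotspot_mode": config.hotspot_mode,
            "n_candidate_sites": config.n_candidate_sites,
        },
        "inputs": {
            "simulate": config.simulate,
            "mutation_table": str(config.mutation_table or ""),
            "counts_table": str(config.counts_table or ""),
            "hotspots_from_panel": config.hotspots_from_panel,
        },
    }
    if config.simulate:
        _simulate_inputs(config, out, manifest)
    if config.ser_dirs:
        summaries = _run_trajectory_arm(config, out, manifest)
        _run_mfa_arm(summaries, out, manifest)
    if config.geometry_pairs:
        _run_geometry_arm(config, out, manifest)
    if config.counts_table or config.hotspots_from_panel or config.mutation_table:
        _run_hotspot_arm(config, out, manifest)
    if config.mutation_table:
        _run_signature_arm(config, out, manifest)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.info("pipeline complete: %s", out)
    return manifest
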