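"""End-to-end orchestration of the synthetic acid-stress study.

``run_pipeline`` executes the enabled stages in dependency order —
expression generation → differential expression → NCA transcription-factor
activities; fluorescence → intracellular pH; PMF scenarios; growth, lipid
and GABA metrics — writing one TSV per stage plus a run summary. Every
random stage derives its own substream from the run seed, so a rerun with
the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import expression, nca, physiology, pmf, reporter, synth
from .errors import ConfigError

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("acidstress")

ALL_STAGES = ("expression_de", "nca", "reporter", "pmf", "growth", "lipids", "gaba")


@dataclass
class RunConfig:
    """Pipeline configuration: stage toggles, presets and seeds."""

    outdir: Path
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    growth_preset: str = "c8_10mM"
    fluorescence_presets: tuple[str, ...] = (
        "hcl_20mM_unadjusted", "c8_longterm", "production",
    )
    lipid_strains: tuple[str, ...] = ("WT", "dcfa", "cfa++")
    lipid_doses: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0)
    gaba_conditions: tuple[str, ...] = ("control", "glutamate", "c8", "c8_glutamate")
    n_perm: int = 10000
    n_boot: int = 1000
    de_genes: int = 500
    de_spiked: int = 10
    topology_path: Path | None = None  # None → built-in demo topology
    shock_ph_i: float = 5.5
    shock_ph_e: float = 7.0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        self.outdir = Path(self.outdir)


def load_config(path) -> RunConfig:
    """Read a YAML run config; missing keys fall back to defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for key in (
        "seed", "growth_preset", "n_perm", "n_boot", "de_genes", "de_spiked",
        "shock_ph_i", "shock_ph_e",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    for key in ("stages", "fluorescence_presets", "lipid_strains",
                "lipid_doses", "gaba_conditions"):
        if key in raw:
            kwargs[key] = tuple(raw[key])
    if "topology" in raw and raw["topology"]:
        kwargs["topology_path"] = Path(raw["topology"])
    if "outdir" not in raw:
        raise ConfigError("config must set outdir")
    return RunConfig(outdir=Path(raw["outdir"]), **kwargs)


def _substreams(seed: int, n: int) -> list[int]:
    """Per-stage integer seeds below 2^31 derived from the run seed."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def run_pipeline(config: RunConfig) -> dict:
    """Run every enabled stage; returns the summary dict (also written to
    ``summary.json``). Raises :class:`ConfigError` naming the stage when an
    enabled stage lacks its inputs."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(ALL_STAGES, _substreams(config.seed, len(ALL_STAGES))))
    summary: dict = {"seed": config.seed, "stages": {}}
    study = None
    topology = None

    def stage_enabled(name: str) -> bool:
        return name in config.stages

    if stage_enabled("nca") and not stage_enabled("expression_de"):
        if config.topology_path is None:
            raise ConfigError(
                "stage 'nca' requires an expression matrix: enable "
                "'expression_de' or supply inputs"
            )

    # --- expression + DE --------------------------------------------------
    if stage_enabled("expression_de"):
        t0 = time.perf_counter()
        study, truth = synth.gen_de_study(
            n_genes=config.de_genes, n_spiked=config.de_spiked,
            seed=seeds["expression_de"],
        )
        res = expression.de_analysis(
            study, n_perm=config.n_perm, seed=seeds["expression_de"]
        )
        hits = expression.call_significant(res)
        _write(study.matrix.reset_index(names="gene_id"), out / "expression_matrix.tsv")
        _write(
            pd.DataFrame({"sample_id": study.conditions.index,
                          "condition": study.conditions.values}),
            out / "sample_sheet.tsv",
        )
        _write(res.reset_index(names="gene_id"), out / "de_results.tsv")
        summary["stages"]["expression_de"] = {
            "n_genes": int(len(res)),
            "n_significant": int(len(hits)),
            "spiked_recovered": int(
                len(set(hits.index) & set(truth.params["spiked_genes"]))
            ),
            "seed": seeds["expression_de"],
        }
        log.info("expression_de done in %.2fs", time.perf_counter() - t0)

    # --- NCA --------------------------------------------------------------
    if stage_enabled("nca"):
        t0 = time.perf_counter()
        if config.topology_path is not None:
            topology = nca.RegulatoryTopology.from_tsv(config.topology_path)
        else:
            topology = synth.demo_topology()
        rng = np.random.default_rng(seeds["nca"])
        # one TF genuinely responds; the rest share their activity across
        # conditions so only replicate noise separates their group means
        base = rng.normal(0.0, 1.0, size=len(topology.tfs))
        true_p = pd.DataFrame(
            {"control": base, "treated": base.copy()}, index=topology.tfs
        )
        true_p.iloc[0, 1] += 3.0
        nca_study, nca_truth = synth.gen_expression(
            topology, true_p, noise_sd=0.05, n_replicates=3, seed=seeds["nca"]
        )
        result = nca.nca_decompose(
            nca_study.matrix, topology, seed=seeds["nca"]
        )
        changes = nca.delta_tfa(
            result.P, nca_study.conditions.loc[result.P.columns],
            n_boot=config.n_boot, seed=seeds["nca"],
        )
        _write(result.P.reset_index(names="tf"), out / "tf_activities.tsv")
        _write(
            pd.DataFrame(
                [{"tf": c.tf, "delta_tfa": c.delta, "direction": c.direction,
                  "p": c.p, "significant": c.significant} for c in changes]
            ),
            out / "tfa_changes.tsv",
        )
        summary["stages"]["nca"] = {
            "n_tfs": len(topology.tfs),
            "converged": bool(result.converged),
            "significant_tfs": [c.tf for c in changes if c.significant],
            "seed": seeds["nca"],
        }
        log.info("nca done in %.2fs", time.perf_counter() - t0)

    # --- reporter pH ------------------------------------------------------
    if stage_enabled("reporter"):
        t0 = time.perf_counter()
        rows = []
        for i, preset in enumerate(config.fluorescence_presets):
            standards, sample, truth = synth.gen_fluorescence(
                preset=preset, seed=seeds["reporter"] + i
            )
            curve = reporter.fit_calibration(standards)
            est = reporter.estimate_ph(sample["readings"], curve)
            rows.append({
                "preset": preset, "ph_estimate": est.value,
                "censored": est.censored, "true_ph": truth.params["true_ph"],
            })
        ph_df = pd.DataFrame(rows)
        _write(ph_df, out / "intracellular_ph.tsv")
        summary["stages"]["reporter"] = {
            "estimates": {r["preset"]: round(r["ph_estimate"], 3) for r in rows},
            "seed": seeds["reporter"],
        }
        log.info("reporter done in %.2fs", time.perf_counter() - t0)

    # --- PMF scenarios ----------------------------------------------------
    if stage_enabled("pmf"):
        t0 = time.perf_counter()
        scenario = pmf.normal_scenario(dose_mM=20.0)
        phases = pmf.run_scenario(
            scenario, measured_pH_i=config.shock_ph_i, pH_e_after=config.shock_ph_e
        )
        rows = []
        for phase, r in phases.items():
            rows.append({
                "label": r.label, "pH_i": r.pH_i, "pH_e": r.pH_e,
                "delta_psi_mV": r.delta_psi, "ph_force_mV": r.ph_force,
                "pmf_mV": r.pmf, "inverted": r.inverted,
                "ion_fold_change": r.ion_fold_change,
            })
        _write(pd.DataFrame(rows), out / "pmf_scenarios.tsv")
        summary["stages"]["pmf"] = {
            "shock_pmf_mV": round(phases["shock"].pmf, 2),
            "adapted_pmf_mV": round(phases["adapted"].pmf, 2),
            "shock_inverted": bool(phases["shock"].inverted),
        }
        log.info("pmf done in %.2fs", time.perf_counter() - t0)

    # --- growth -----------------------------------------------------------
    if stage_enabled("growth"):
        t0 = time.perf_counter()
        ctrl, trt, truth = synth.gen_growth_curves(
            preset=config.growth_preset, seed=seeds["growth"]
        )
        mu_c = physiology.fit_growth_rate(ctrl)
        mu_t = physiology.fit_growth_rate(trt)
        inhib = physiology.percent_inhibition(mu_c, mu_t)
        _write(
            pd.DataFrame({
                "time_h": ctrl.times, "od550_control": ctrl.od,
                "od550_treated": trt.od,
            }),
            out / "growth_curves.tsv",
        )
        summary["stages"]["growth"] = {
            "mu_control": round(mu_c, 4), "mu_treated": round(mu_t, 4),
            "percent_inhibition": round(inhib, 2), "seed": seeds["growth"],
        }
        log.info("growth done in %.2fs", time.perf_counter() - t0)

    # --- lipids -----------------------------------------------------------
    if stage_enabled("lipids"):
        t0 = time.perf_counter()
        rows = []
        for i, strain in enumerate(config.lipid_strains):
            for j, dose in enumerate(config.lipid_doses):
                profile, _ = synth.gen_lipid_profiles(
                    strain=strain, dose_mM=dose,
                    seed=seeds["lipids"] + 100 * i + j,
                )
                m = physiology.lipid_metrics(profile)
                rows.append({
                    "strain": strain, "dose_mM": dose,
                    "su_ratio": m.su_ratio, "avg_length": m.average_length,
                    "cyclopropane_molpct": m.cyclopropane_molpct,
                })
        lip_df = pd.DataFrame(rows)
        _write(lip_df, out / "lipid_metrics.tsv")
        zero = lip_df[lip_df["dose_mM"] == 0].set_index("strain")
        summary["stages"]["lipids"] = {
            "cyclopropane_molpct_dose0": {
                s: round(v, 2) for s, v in zero["cyclopropane_molpct"].items()
            },
            "seed": seeds["lipids"],
        }
        log.info("lipids done in %.2fs", time.perf_counter() - t0)

    # --- GABA -------------------------------------------------------------
    if stage_enabled("gaba"):
        t0 = time.perf_counter()
        rows = []
        for i, cond in enumerate(config.gaba_conditions):
            m, _ = synth.gen_gaba(condition=cond, seed=seeds["gaba"] + i)
            total, protons = physiology.gaba_balance(m)
            rows.append({
                "condition": cond, "intracellular": m.intracellular,
                "extracellular": m.extracellular, "total": total,
                "protons_sunk_lower_bound": protons,
            })
        _write(pd.DataFrame(rows), out / "gaba_balance.tsv")
        summary["stages"]["gaba"] = {
            "totals": {r["condition"]: round(r["total"], 2) for r in rows},
            "seed": seeds["gaba"],
        }
        log.info("gaba done in %.2fs", time.perf_counter() - t0)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
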