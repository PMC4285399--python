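"""End-to-end synthetic study: generate, estimate, score, model, mediate, correct.

``run_pipeline`` executes the whole workflow on simulated data with known
ground truth and returns a :class:`RunReport` whose qualitative table states
the planted dissociation: the signature mediates temperature -> pain but not
regulation -> pain, while the m1 -> m2 chain mediates regulation -> pain
(and the reversed chain does not).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import generate_design
from .mediation import (
    mediation_brain_search,
    multilevel_mediation,
    multilevel_three_path,
)
from .multilevel import fit_subject_linear, fit_subject_logistic, group_level_test
from .params import GroundTruthParams, TEMP_CENTER_C
from .simulate import simulate_trial_responses, simulate_voxel_brain
from .clusters import monte_carlo_cluster_threshold
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "make_report"]


@dataclass
class PipelineConfig:
    truth: GroundTruthParams = field(default_factory=GroundTruthParams)
    n_subjects: int = 20
    n_boot: int = 2000
    alpha: float = 0.05
    seed: int = 0
    do_brain_search: bool = True
    brain_grid: tuple = (12, 12, 12)
    cluster_n_iter: int = 1000
    search_primary_p: float = 0.005
    from_timeseries: bool = False
    output_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["truth"] = self.truth.to_dict()
        d["brain_grid"] = list(self.brain_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["truth"] = GroundTruthParams.from_dict(d["truth"])
        d["brain_grid"] = tuple(d.get("brain_grid", (12, 12, 12)))
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class RunReport:
    config: dict
    behavioral: dict
    mediation: dict
    recovery: list
    search: dict
    provenance: dict
    skipped_stages: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, default=_jsonify)
        if path is not None:
            Path(path).write_text(text)
        return text

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()

    def to_text(self) -> str:
        lines = [
            f"painpath run report (package {self.provenance.get('version')})",
            f"seed={self.config.get('seed')} subjects={self.config.get('n_subjects')}",
            "",
            "Behavioral group effects (two-tailed):",
        ]
        for model, table in self.behavioral.items():
            if not table:
                continue
            lines.append(f"  [{model}]")
            for row in table:
                lines.append(
                    f"    {row['predictor']:<14s} beta={row['beta_hat']:+8.3f} "
                    f"t({row['df']})={row['t']:+7.2f} p={row['p']:.4f}"
                )
        lines.append("")
        lines.append("Mediation models:")
        for name, res in self.mediation.items():
            if res is None:
                lines.append(f"  {name}: SKIPPED")
                continue
            flag = "significant" if res["significant"] else "not significant"
            lines.append(f"  {name}: {flag}")
            for pname, s in res["paths"].items():
                lines.append(
                    f"    {pname:<8s} {s['estimate']:+9.4f} (SE {s['se']:.4f}) "
                    f"p={s['p']:.4f}"
                )
        lines.append("")
        lines.append("Ground-truth recovery (truth vs estimate, 95% bootstrap CI):")
        for row in self.recovery:
            inside = "ok" if row["within_ci"] else "OUTSIDE"
            lines.append(
                f"  {row['parameter']:<14s} truth={row['truth']:+8.3f} "
                f"est={row['estimate']:+8.3f} CI=[{row['ci_low']:+.3f}, "
                f"{row['ci_high']:+.3f}] {inside}"
            )
        if self.search:
            lines.append("")
            lines.append(
                "Voxel-wise second-mediator search: "
                f"{self.search.get('n_significant_voxels', 0)} significant voxels "
                f"after cluster correction (k_min={self.search.get('k_min')}), "
                f"Dice vs planted cluster = {self.search.get('dice'):.3f}"
            )
        if self.skipped_stages:
            lines.append("")
            lines.append("Skipped stages: " + ", ".join(self.skipped_stages))
        return "\n".join(lines) + "\n"


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _mediation_to_dict(res) -> dict:
    return {
        "paths": {
            name: {
                "estimate": s.estimate, "se": s.se, "p": s.p,
                "ci_low": s.ci_low, "ci_high": s.ci_high,
            }
            for name, s in res.paths.items()
        },
        "significant": bool(res.significant),
        "joint_significant": res.joint_significant,
        "n_boot": res.n_boot,
        "seed": res.seed,
        "n_subjects": res.n_subjects,
        "alpha": res.alpha,
    }


def _stage_seeds(seed: int, n: int = 16) -> list:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _betas_from_timeseries(dataset, seed: int) -> pd.DataFrame:
    """Re-estimate the signature scalar through the single-trial GLM path.

    For every run, simulate a one-voxel BOLD series whose per-trial
    amplitudes are the subject's signature responses, rebuild the matching
    single-trial design, and replace ``sig`` with the recovered beta series;
    trials with VIF > 2.5 get the ``excluded`` flag.
    """
    from .glm import NuisanceSpec, build_single_trial_design, estimate_single_trial_betas
    from .simulate import simulate_timeseries

    rng = np.random.default_rng(seed)
    trials = dataset.trials
    tr = 2.0
    for (subject, run), d in trials.groupby(["subject", "run"]):
        amps = d["sig"].to_numpy()
        series, events = simulate_timeseries(
            d, amps, noise_sd=0.05, drift_slope=0.0, tr=tr,
            seed=int(rng.integers(2**31)),
        )
        design = build_single_trial_design(
            events, tr=tr, n_volumes=len(series), nuisance_spec=NuisanceSpec()
        )
        bs = estimate_single_trial_betas(series, design)
        trials.loc[d.index, "sig"] = bs.betas
        trials.loc[d.index, "vif"] = bs.vif
        trials.loc[d.index, "excluded"] = bs.excluded
    return trials


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full synthetic study described by ``config``."""
    t0 = time.time()
    seeds = _stage_seeds(config.seed)
    skipped = []

    # --- stage 1: design + trial responses -------------------------------
    design = generate_design(config.n_subjects, seed=seeds[0])
    dataset = simulate_trial_responses(design, config.truth, seed=seeds[1])
    trials = dataset.trials
    if config.from_timeseries:
        trials = _betas_from_timeseries(dataset, seed=seeds[2])
    trials = trials.copy()
    trials["temp_centered"] = trials["temp_c"] - TEMP_CENTER_C

    # --- stage 2: behavioral multilevel GLM ------------------------------
    run_order = (
        trials[trials["run"] == 3]
        .groupby("subject")["run_type"].first()
        .map({"regulate_up": 1, "regulate_down": -1})
        .to_frame("reg_order")
    )
    lin = [fit_subject_linear(d) for _, d in trials.groupby("subject")]
    behavioral = {
        "linear": group_level_test(lin, run_order).reset_index().to_dict("records")
    }
    logi = [fit_subject_logistic(d) for _, d in trials.groupby("subject")]
    usable = [c for c in logi if c.converged]
    if len(usable) >= 3:
        behavioral["logistic"] = (
            group_level_test(logi, run_order).reset_index().to_dict("records")
        )
    else:
        behavioral["logistic"] = []
        skipped.append("behavioral_logistic")

    # --- stage 3: mediation ----------------------------------------------
    med = {}
    med_objs = {}
    med_objs["temp_sig_pain"] = multilevel_mediation(
        trials, x="temp_centered", m="sig", y="rating", covariates=["reg_code"],
        n_boot=config.n_boot, seed=seeds[3], alpha=config.alpha,
    )
    med_objs["reg_sig_pain"] = multilevel_mediation(
        trials, x="reg_code", m="sig", y="rating", covariates=["temp_centered"],
        n_boot=config.n_boot, seed=seeds[4], alpha=config.alpha,
    )
    med_objs["reg_m1_m2_pain"] = multilevel_three_path(
        trials, x="reg_code", m1="m1", m2="m2", y="rating",
        covariates=["temp_centered", "sig"],
        n_boot=config.n_boot, seed=seeds[5], alpha=config.alpha,
    )
    med_objs["reg_m2_m1_pain_reversed"] = multilevel_three_path(
        trials, x="reg_code", m1="m2", m2="m1", y="rating",
        covariates=["temp_centered", "sig"],
        n_boot=config.n_boot, seed=seeds[6], alpha=config.alpha,
    )
    med = {k: _mediation_to_dict(v) for k, v in med_objs.items()}

    # --- stage 4: ground-truth recovery ----------------------------------
    truth = config.truth
    recovery_map = [
        ("temp_to_pain", truth.temp_to_pain, med_objs["temp_sig_pain"].paths["c_prime"]),
        ("temp_to_sig", truth.temp_to_sig, med_objs["temp_sig_pain"].paths["a"]),
        ("sig_to_pain", truth.sig_to_pain, med_objs["temp_sig_pain"].paths["b"]),
        ("reg_to_m1", truth.reg_to_m1, med_objs["reg_m1_m2_pain"].paths["b1"]),
        ("m1_to_m2", truth.m1_to_m2, med_objs["reg_m1_m2_pain"].paths["b2"]),
        ("m2_to_pain", truth.m2_to_pain, med_objs["reg_m1_m2_pain"].paths["b3"]),
    ]
    recovery = [
        {
            "parameter": name, "truth": tv, "estimate": s.estimate,
            "se": s.se, "ci_low": s.ci_low, "ci_high": s.ci_high,
            "within_2se": bool(abs(s.estimate - tv) <= 2 * s.se),
            "within_ci": bool(s.ci_low <= tv <= s.ci_high),
        }
        for name, tv, s in recovery_map
    ]

    # --- stage 5: voxel-wise mediator search + cluster correction --------
    search: dict = {}
    if config.do_brain_search:
        search = _brain_search_stage(
            design, config, seeds[7], seeds[8], seeds[9]
        )
    else:
        skipped.append("brain_search")

    provenance = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds[:10],
        "duration_s": round(time.time() - t0, 3),
    }
    report = make_report(
        {
            "config": config.to_dict(),
            "behavioral": behavioral,
            "mediation": med,
            "recovery": recovery,
            "search": search,
            "provenance": provenance,
            "skipped_stages": skipped,
        }
    )
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        trials.to_csv(out / "trials.csv", index=False)
        config.to_yaml(out / "config.yaml")
        report.to_json(out / "report.json")
        (out / "report.txt").write_text(report.to_text())
    return report


def _brain_search_stage(design, config, seed_brain, seed_search, seed_mc) -> dict:
    """Planted-cluster second-mediator search with cluster-extent correction."""
    subject_data = []
    brain = None
    rng = np.random.default_rng(seed_brain)
    for subject, d in design.groupby("subject"):
        b, _, ds = simulate_voxel_brain(
            d, config.truth, grid_shape=config.brain_grid,
            seed=int(rng.integers(2**31)),
        )
        brain = b  # mask/cluster layout is identical across subjects
        flat = b.per_trial_betas[:, b.mask]
        subject_data.append(
            {
                "x": ds.trials["reg_code"].to_numpy(float),
                "y": ds.trials["rating"].to_numpy(float),
                "betas": flat,
                "cov": np.column_stack(
                    [ds.trials["temp_c"].to_numpy(float) - TEMP_CENTER_C,
                     ds.sig_response]
                ),
                "m_fixed": ds.m1,
            }
        )
    res = mediation_brain_search(
        subject_data, mode="search_m2", n_boot=config.n_boot,
        seed=seed_search, alpha=config.alpha,
    )
    # cluster-extent correction of the jointly significant voxel set
    thr = monte_carlo_cluster_threshold(
        brain.mask, fwhm_mm=0.0, primary_p=config.search_primary_p,
        alpha_fwer=config.alpha, n_iter=config.cluster_n_iter, seed=seed_mc,
        voxel_size_mm=brain.voxel_size,
    )
    pmap = np.full(brain.grid_shape, np.nan)
    pmap[brain.mask] = res["p_product"]
    # cluster-forming threshold on the product map; joint significance of
    # the three constituent paths at the conventional level
    joint = np.zeros(brain.grid_shape, dtype=bool)
    joint[brain.mask] = (
        (res["p_product"] < config.search_primary_p)
        & (res["p_b1"] < config.alpha)
        & (res["p_b2"] < config.alpha)
        & (res["p_b3"] < config.alpha)
    )
    lab, n_lab = ndimage.label(joint)
    surviving = np.zeros_like(joint)
    for cid in range(1, n_lab + 1):
        vox = lab == cid
        if vox.sum() >= thr.k_min:
            surviving |= vox
    true_m2 = brain.cluster_mask(brain.M2)
    inter = (surviving & true_m2).sum()
    dice = 2.0 * inter / (surviving.sum() + true_m2.sum()) if (
        surviving.sum() + true_m2.sum()
    ) else 0.0
    return {
        "k_min": int(thr.k_min),
        "primary_p": config.search_primary_p,
        "n_significant_voxels": int(surviving.sum()),
        "n_true_m2_voxels": int(true_m2.sum()),
        "dice": float(dice),
        "n_skipped_voxels": int(res["skipped"].sum()),
    }


def make_report(artifacts: dict) -> RunReport:
    """Assemble a RunReport; missing artifacts are flagged, never fatal."""
    required = ["config", "behavioral", "mediation", "recovery", "search",
                "provenance"]
    skipped = list(artifacts.get("skipped_stages", []))
    filled = {}
    for key in required:
        if key not in artifacts or artifacts[key] is None:
            skipped.append(key)
            filled[key] = {} if key != "recovery" else []
        else:
            filled[key] = artifacts[key]
    # internal consistency: significance flags must match stored p-values
    for name, res in filled["mediation"].items():
        if not res:
            continue
        alpha = res.get("alpha", 0.05)
        product = "ab" if "ab" in res["paths"] else "product"
        expect = res["paths"][product]["p"] < alpha
        if res.get("joint_significant") is not None:
            expect = expect and res["joint_significant"]
        if bool(res["significant"]) != bool(expect):
            raise ValueError(f"inconsistent significance flag in {name!r}")
    return RunReport(
        config=filled["config"],
        behavioral=filled["behavioral"],
        mediation=filled["mediation"],
        recovery=filled["recovery"],
        search=filled["search"],
        provenance=filled["provenance"],
        skipped_stages=skipped,
    )
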