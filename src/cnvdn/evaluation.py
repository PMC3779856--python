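"""Simulation study: TPR/FPR of de novo mutation detection across methods.

For each measurement-noise SD in the design, the study simulates
replicated cohorts of nuclear families, runs the chosen detector and
scores family-level flags against the ground truth.  The Bayesian
detectors additionally yield member-level operating characteristics
split by mutation type (gain vs loss).

Detection engines
-----------------
``bayes-enumerate``
    Exact family posteriors by enumeration (the default; posterior
    probabilities are computed without Monte Carlo error, so study-sized
    replication counts are tractable on one CPU).
``bayes-mcmc``
    The Metropolis-within-Gibbs sampler; equivalent to enumeration up to
    Monte Carlo error, available for fidelity runs.
``nearest-integer``
    The rounding + Mendelian-consistency comparator (family flags only).

Family-level flags use the strict rule: a family counts as detected when
any offspring's posterior probability of insertion or deletion exceeds
the threshold.  The family-level FPR denominator is all simulated
families without a true de novo event, pooled across replications;
member-level rates count every offspring once per replication.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import simulator
from .baseline_nearest_integer import mendelian_consistent
from .cnv_model import ModelConfig, build_tables, posterior_from_logliks
from .inference import DEFAULT_THRESHOLDS, MCMCConfig, run_detection_mcmc
from .simulator import SimConfig

__all__ = [
    "StudyDesign",
    "OperatingCharacteristics",
    "run_study",
    "score_member_level",
    "plot_operating_characteristics",
]

METHODS = ("bayes-enumerate", "bayes-mcmc", "nearest-integer")


@dataclass(frozen=True)
class StudyDesign:
    """Grid of simulation settings and the detection method to evaluate.

    ``sigma_handling`` controls the Bayesian engines' measurement SD:
    ``"truth"`` fixes it at the simulating value, ``"plugin"`` uses the
    pooled replicate SD of each cohort.  ``mutation_prior=None`` applies
    the rule-of-thumb 1 / (number of genotyped offspring in a cohort).
    """

    sds: tuple[float, ...] = (0.15, 0.20, 0.25)
    n_replications: int = 1000
    method: str = "bayes-enumerate"
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    sim: SimConfig = field(default_factory=SimConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    sigma_handling: str = "truth"
    mcmc: MCMCConfig | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_replications < 1:
            raise ValueError("n_replications must be >= 1")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.sigma_handling not in {"truth", "plugin"}:
            raise ValueError("sigma_handling must be 'truth' or 'plugin'")


@dataclass
class OperatingCharacteristics:
    """Aggregated detection rates with Monte Carlo standard errors.

    ``family_rates`` columns: sd, method, threshold (NaN for the
    baseline), tpr, fpr, tpr_se, fpr_se, n_mut_families, n_null_families.
    ``member_rates`` (Bayesian methods only) columns: sd, threshold,
    type, tpr, fpr, tpr_se, fpr_se, n_carriers, n_non_carriers.
    """

    family_rates: pd.DataFrame
    member_rates: pd.DataFrame | None = None

    def table4(self) -> pd.DataFrame:
        """Family-level rates pivoted in the conventional layout."""
        fr = self.family_rates.copy()
        fr["threshold"] = fr["threshold"].fillna("nearest-integer")
        return fr.pivot_table(
            index="sd", columns="threshold", values=["tpr", "fpr"], sort=True
        )

    def save(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.family_rates.to_csv(d / "family_rates.tsv", sep="\t", index=False)
        if self.member_rates is not None:
            self.member_rates.to_csv(d / "member_rates.tsv", sep="\t", index=False)


def _binom_se(p: float, n: int) -> float:
    return float(np.sqrt(p * (1 - p) / n)) if n > 0 else float("nan")


def _rate(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def _nearest_integer_flags(arr: dict) -> np.ndarray:
    rp = np.maximum(np.round(arr["meas_par"].mean(axis=2)), 0).astype(int)
    rk = np.maximum(np.round(arr["meas_kid"].mean(axis=2)), 0).astype(int)
    F = rp.shape[0]
    flags = np.empty(F, dtype=bool)
    for i in range(F):
        flags[i] = not mendelian_consistent(rp[i, 0], rp[i, 1], list(rk[i]))
    return flags


def _enumerate_posteriors(arr: dict, sd: float, tables, mut: float) -> dict:
    """Batch exact posteriors for a simulated cohort at fixed sigma."""
    G = tables.n_grid
    grid = np.arange(G)

    def ll(meas: np.ndarray) -> np.ndarray:
        # (..., R) measurements -> (..., G) Gaussian log-likelihood tables
        sse = ((meas[..., None] - grid) ** 2).sum(axis=-2)
        return -sse / (2 * sd**2)

    par_ll = ll(arr["meas_par"])
    kid_ll = ll(arr["meas_kid"])
    kid_mask = np.ones(kid_ll.shape[:2], dtype=bool)
    return posterior_from_logliks(par_ll, kid_ll, kid_mask, tables, mut, mut)


def _mcmc_posteriors(arr: dict, cfg: SimConfig, design: StudyDesign, seed) -> dict:
    """Per-rep detection MCMC; returns the same keyed arrays as enumeration."""
    ped, ms = _containers_from_arrays(arr, cfg)
    mcmc = replace(
        design.mcmc or MCMCConfig(),
        seed=seed,
        sigma_fixed=cfg.meas_sd if design.sigma_handling == "truth" else None,
    )
    draws = run_detection_mcmc(ped, ms, design.model, mcmc)
    off = draws.individuals[draws.individuals["role"] == "offspring"].sort_values(
        ["family_id", "individual_id"]
    )
    F, J = arr["cn_kid"].shape
    return {
        "p_ins": off["p_ins"].to_numpy().reshape(F, J),
        "p_del": off["p_del"].to_numpy().reshape(F, J),
    }


def _containers_from_arrays(arr: dict, cfg: SimConfig):
    """Rebuild pedigree/measurement containers from one marker's arrays so
    that the MCMC engine sees exactly the data the batch engine saw."""
    from .pedigree_io import Family, Individual, MeasurementSet, Pedigree

    F, J, R = arr["meas_kid"].shape
    ped = Pedigree()
    rows = []
    for i in range(F):
        fid = f"fam{i + 1:04d}"
        father, mother = f"{fid}_f", f"{fid}_m"
        fam = Family(family_id=fid)
        fam.members[father] = Individual(fid, father, sex=1)
        fam.members[mother] = Individual(fid, mother, sex=2)
        for p, iid in enumerate((father, mother)):
            for k in range(R):
                rows.append((iid, "CNV1", k + 1, arr["meas_par"][i, p, k]))
        for j in range(J):
            child = f"{fid}_c{j + 1}"
            fam.members[child] = Individual(
                fid, child, father_id=father, mother_id=mother
            )
            for k in range(R):
                rows.append((child, "CNV1", k + 1, arr["meas_kid"][i, j, k]))
        ped.families[fid] = fam
    ms = MeasurementSet(
        pd.DataFrame(rows, columns=["individual_id", "marker_id", "replicate", "value"])
    )
    return ped, ms


def run_study(design: StudyDesign) -> OperatingCharacteristics:
    """Run the full replication study and aggregate operating characteristics."""
    tables = build_tables(design.model.max_allele, design.model.allele_prior_mean)
    n_off_total = design.sim.n_families * design.sim.n_offspring
    mut = design.model.resolve_mutation_prior(n_off_total)
    seed = 0 if design.seed is None else int(design.seed)

    fam_rows, mem_rows = [], []
    for sd in design.sds:
        cfg = replace(design.sim, meas_sd=sd)
        rng = np.random.default_rng([seed, int(round(sd * 1000))])
        thresholds = design.thresholds
        fam_tp = {t: 0 for t in thresholds}
        fam_fp = {t: 0 for t in thresholds}
        ni_tp = ni_fp = 0
        n_mut_fam = n_null_fam = 0
        mem = {
            (t, typ): [0, 0, 0, 0]  # tp, fn, fp, tn
            for t in thresholds
            for typ in ("gain", "loss")
        }
        for rep in range(design.n_replications):
            arr = simulator._simulate_marker_arrays(cfg, rng)
            truth_fam = (arr["label"] != 0).any(axis=1)
            n_mut_fam += int(truth_fam.sum())
            n_null_fam += int((~truth_fam).sum())

            if design.method == "nearest-integer":
                flags = _nearest_integer_flags(arr)
                ni_tp += int((flags & truth_fam).sum())
                ni_fp += int((flags & ~truth_fam).sum())
                continue

            if design.method == "bayes-enumerate":
                sig = (
                    sd
                    if design.sigma_handling == "truth"
                    else _plugin_sd(arr)
                )
                post = _enumerate_posteriors(arr, sig, tables, mut)
            else:
                rep_seed = int(
                    (seed * 1009 + round(sd * 1000)) * 100_003 + rep
                ) % (2**31)
                post = _mcmc_posteriors(arr, cfg, design, seed=rep_seed)
            p_ins, p_del = post["p_ins"], post["p_del"]
            for t in thresholds:
                hit = (p_ins > t) | (p_del > t)
                fam_hit = hit.any(axis=1)
                fam_tp[t] += int((fam_hit & truth_fam).sum())
                fam_fp[t] += int((fam_hit & ~truth_fam).sum())
                for typ, p, code in (("gain", p_ins, 1), ("loss", p_del, 2)):
                    carrier = arr["label"] == code
                    call = p > t
                    rec = mem[(t, typ)]
                    rec[0] += int((call & carrier).sum())
                    rec[1] += int((~call & carrier).sum())
                    rec[2] += int((call & ~carrier).sum())
                    rec[3] += int((~call & ~carrier).sum())

        if design.method == "nearest-integer":
            tpr, fpr = _rate(ni_tp, n_mut_fam), _rate(ni_fp, n_null_fam)
            fam_rows.append(
                (
                    sd, design.method, np.nan, tpr, fpr,
                    _binom_se(tpr, n_mut_fam), _binom_se(fpr, n_null_fam),
                    n_mut_fam, n_null_fam,
                )
            )
        else:
            for t in thresholds:
                tpr = _rate(fam_tp[t], n_mut_fam)
                fpr = _rate(fam_fp[t], n_null_fam)
                fam_rows.append(
                    (
                        sd, design.method, t, tpr, fpr,
                        _binom_se(tpr, n_mut_fam), _binom_se(fpr, n_null_fam),
                        n_mut_fam, n_null_fam,
                    )
                )
                for typ in ("gain", "loss"):
                    tp, fn, fp, tn = mem[(t, typ)]
                    m_tpr, m_fpr = _rate(tp, tp + fn), _rate(fp, fp + tn)
                    mem_rows.append(
                        (
                            sd, t, typ, m_tpr, m_fpr,
                            _binom_se(m_tpr, tp + fn), _binom_se(m_fpr, fp + tn),
                            tp + fn, fp + tn,
                        )
                    )

    family_rates = pd.DataFrame(
        fam_rows,
        columns=[
            "sd", "method", "threshold", "tpr", "fpr",
            "tpr_se", "fpr_se", "n_mut_families", "n_null_families",
        ],
    )
    member_rates = (
        pd.DataFrame(
            mem_rows,
            columns=[
                "sd", "threshold", "type", "tpr", "fpr",
                "tpr_se", "fpr_se", "n_carriers", "n_non_carriers",
            ],
        )
        if mem_rows
        else None
    )
    return OperatingCharacteristics(family_rates, member_rates)


def _plugin_sd(arr: dict) -> float:
    meas = np.concatenate(
        [arr["meas_par"].reshape(-1, arr["meas_par"].shape[-1]),
         arr["meas_kid"].reshape(-1, arr["meas_kid"].shape[-1])]
    )
    if meas.shape[1] < 2:
        raise ValueError("plugin sigma needs >= 2 replicates per individual")
    resid = meas - meas.mean(axis=1, keepdims=True)
    return float(np.sqrt((resid**2).sum() / (meas.shape[0] * (meas.shape[1] - 1))))


def score_member_level(
    posteriors: pd.DataFrame,
    truth: pd.DataFrame,
    threshold: float,
    type: str,
) -> tuple[float, float]:
    """Member-level (TPR, FPR) for one mutation type at one threshold.

    ``posteriors`` must carry per-offspring ``p_ins``/``p_del`` columns
    (Bayesian engines only — the nearest-integer baseline has no
    member-level output and raises).  ``truth`` is a frame with
    individual_id, marker_id and label columns; TPR is computed over
    members carrying a type-matching mutation, FPR over members without.
    """
    if type not in {"gain", "loss"}:
        raise ValueError("type must be 'gain' or 'loss'")
    col = "p_ins" if type == "gain" else "p_del"
    if col not in posteriors.columns:
        raise ValueError(
            "posteriors lack member-level mutation probabilities; the "
            "nearest-integer baseline yields family-level flags only"
        )
    off = posteriors[posteriors.get("role", "offspring") == "offspring"]
    merged = off.merge(
        truth[["individual_id", "marker_id", "label"]],
        on=["individual_id", "marker_id"],
        how="inner",
    )
    carrier = merged["label"] == type
    call = merged[col] > threshold
    tpr = _rate(int((call & carrier).sum()), int(carrier.sum()))
    fpr = _rate(int((call & ~carrier).sum()), int((~carrier).sum()))
    return tpr, fpr


def plot_operating_characteristics(oc: OperatingCharacteristics, path=None):
    """TPR/FPR vs threshold per SD; returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharex=True)
    fr = oc.family_rates.dropna(subset=["threshold"])
    for sd, grp in fr.groupby("sd"):
        axes[0].plot(grp["threshold"], grp["tpr"], marker="o", label=f"SD={sd:g}")
        axes[1].plot(grp["threshold"], grp["fpr"], marker="o", label=f"SD={sd:g}")
    for ax, name in zip(axes, ["family TPR", "family FPR"]):
        ax.set_xlabel("posterior threshold")
        ax.set_ylabel(name)
        ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
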