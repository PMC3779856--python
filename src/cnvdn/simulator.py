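"""Synthetic nuclear-family CNV datasets with known mutation ground truth.

The generator reproduces the simulation world used to benchmark the
detection model: a population of nuclear families (default 200 families
of four: two parents, two offspring), one or more independent CNV
markers, founder haplotype copy number 2 with probability
``insertion_freq`` (default 0.01) and 1 otherwise, Mendelian transmission
of one haplotype per parent, and a per-offspring de novo event drawn as a
single categorical outcome: copy gain with probability ``p_gain``, copy
loss with ``p_loss`` (defaults 0.005 each), otherwise none.  Measurements
are the true integer CN plus Gaussian noise with SD ``meas_sd``
(benchmark settings 0.15, 0.20, 0.25), replicated ``n_replicates`` times
(default 2, the first-stage design).

Disease status for association testing is an optional extension: a
logistic model with a family-specific random intercept generates
offspring affection; parents' status is left missing by default, matching
an analysis that uses only the children's disease status.

All randomness flows through a single :class:`numpy.random.Generator`;
identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree_io import Family, Individual, MeasurementSet, Pedigree

__all__ = [
    "SimConfig",
    "AssocParams",
    "SimTruth",
    "simulate_families",
    "simulate_disease",
    "apply_two_stage",
]

LABELS = ("none", "gain", "loss")


@dataclass(frozen=True)
class AssocParams:
    """Logistic disease-model parameters: logit(p) = alpha + beta*C + gamma*X + b_i."""

    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0
    re_sd: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    n_families: int = 200
    n_offspring: int = 2           # family of four: 2 parents + 2 offspring
    insertion_freq: float = 0.01   # founder haplotype CN 2 with this probability
    p_gain: float = 0.005
    p_loss: float = 0.005
    meas_sd: float = 0.15
    n_replicates: int = 2
    n_markers: int = 1
    assoc: AssocParams | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("insertion_freq", "p_gain", "p_loss"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.p_gain + self.p_loss > 1.0:
            raise ValueError("p_gain + p_loss must not exceed 1")
        if self.n_families < 1 or self.n_offspring < 1 or self.n_replicates < 1:
            raise ValueError("n_families, n_offspring, n_replicates must be >= 1")
        if self.meas_sd <= 0:
            raise ValueError("meas_sd must be positive")


@dataclass
class SimTruth:
    """Ground-truth latent state, one row per individual per marker.

    Columns: family_id, individual_id, marker_id, role (father/mother/
    offspring), hap1, hap2 (founder haplotypes or the two inherited
    haplotypes for offspring), true_cn, label in {none, gain, loss}.
    """

    data: pd.DataFrame

    def family_flags(self) -> pd.Series:
        """contains_mutation per family: OR over offspring labels != none."""
        d = self.data
        return (
            (d["label"] != "none")
            .groupby(d["family_id"])
            .any()
            .rename("contains_mutation")
        )

    def offspring(self) -> pd.DataFrame:
        return self.data[self.data["role"] == "offspring"]


def _simulate_marker_arrays(cfg: SimConfig, rng: np.random.Generator) -> dict:
    """Vectorized single-marker draw; the array form used by the study loop."""
    F, J, R = cfg.n_families, cfg.n_offspring, cfg.n_replicates
    # founder haplotypes: (family, parent, haplotype)
    hap_par = np.where(rng.random((F, 2, 2)) < cfg.insertion_freq, 2, 1)
    cn_par = hap_par.sum(axis=2)
    # each offspring picks one haplotype per parent uniformly
    pick = rng.integers(0, 2, size=(F, J, 2))
    inherited = np.take_along_axis(
        hap_par[:, None, :, :].repeat(J, axis=1).reshape(F, J, 2, 2),
        pick[..., None],
        axis=3,
    )[..., 0]  # (F, J, 2)
    cn_inh = inherited.sum(axis=2)
    u = rng.random((F, J))
    label = np.zeros((F, J), dtype=int)
    label[u < cfg.p_gain] = 1
    label[(u >= cfg.p_gain) & (u < cfg.p_gain + cfg.p_loss)] = 2
    cn_kid = np.maximum(cn_inh + (label == 1) - (label == 2), 0)
    meas_par = cn_par[..., None] + rng.normal(0.0, cfg.meas_sd, size=(F, 2, R))
    meas_kid = cn_kid[..., None] + rng.normal(0.0, cfg.meas_sd, size=(F, J, R))
    return {
        "hap_par": hap_par,
        "inherited": inherited,
        "cn_par": cn_par,
        "cn_kid": cn_kid,
        "label": label,
        "meas_par": meas_par,
        "meas_kid": meas_kid,
    }


def _ids(cfg: SimConfig) -> tuple[list[str], list[list[str]]]:
    fids = [f"fam{i + 1:04d}" for i in range(cfg.n_families)]
    iids = [
        [f"{fid}_f", f"{fid}_m"] + [f"{fid}_c{j + 1}" for j in range(cfg.n_offspring)]
        for fid in fids
    ]
    return fids, iids


def simulate_families(
    config: SimConfig, rng: np.random.Generator | int | None = None
) -> tuple[Pedigree, MeasurementSet, SimTruth]:
    """Draw a complete synthetic dataset: pedigree, measurements, truth.

    If ``config.assoc`` is set, offspring affection statuses are drawn
    from the logistic disease model and stored in the pedigree (parents'
    statuses stay missing).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)

    fids, iids = _ids(config)
    markers = [f"CNV{m + 1}" for m in range(config.n_markers)]
    per_marker = [_simulate_marker_arrays(config, rng) for _ in markers]

    ped = Pedigree()
    for i, fid in enumerate(fids):
        fam = Family(family_id=fid)
        father, mother = iids[i][0], iids[i][1]
        fam.members[father] = Individual(fid, father, sex=1)
        fam.members[mother] = Individual(fid, mother, sex=2)
        for child in iids[i][2:]:
            fam.members[child] = Individual(
                fid, child, father_id=father, mother_id=mother
            )
        ped.families[fid] = fam

    truth_rows = []
    meas_rows = []
    for mi, marker in enumerate(markers):
        arr = per_marker[mi]
        for i, fid in enumerate(fids):
            for p, role in enumerate(("father", "mother")):
                truth_rows.append(
                    (
                        fid, iids[i][p], marker, role,
                        arr["hap_par"][i, p, 0], arr["hap_par"][i, p, 1],
                        arr["cn_par"][i, p], "none",
                    )
                )
                for k in range(config.n_replicates):
                    meas_rows.append(
                        (iids[i][p], marker, k + 1, arr["meas_par"][i, p, k])
                    )
            for j in range(config.n_offspring):
                child = iids[i][2 + j]
                truth_rows.append(
                    (
                        fid, child, marker, "offspring",
                        arr["inherited"][i, j, 0], arr["inherited"][i, j, 1],
                        arr["cn_kid"][i, j], LABELS[arr["label"][i, j]],
                    )
                )
                for k in range(config.n_replicates):
                    meas_rows.append(
                        (child, marker, k + 1, arr["meas_kid"][i, j, k])
                    )

    truth = SimTruth(
        pd.DataFrame(
            truth_rows,
            columns=[
                "family_id", "individual_id", "marker_id", "role",
                "hap1", "hap2", "true_cn", "label",
            ],
        )
    )
    ms = MeasurementSet(
        pd.DataFrame(
            meas_rows, columns=["individual_id", "marker_id", "replicate", "value"]
        )
    )

    if config.assoc is not None:
        disease = simulate_disease(ped, truth, config.assoc, rng)
        _attach_disease(ped, disease)

    return ped, ms, truth


def _attach_disease(ped: Pedigree, disease: pd.DataFrame) -> None:
    from dataclasses import replace

    table = disease.set_index("individual_id")
    for fam in ped.families.values():
        for iid, ind in list(fam.members.items()):
            if iid in table.index:
                row = table.loc[iid]
                fam.members[iid] = replace(
                    ind,
                    affected=int(row["affected"]),
                    covariates=(float(row["covariate"]),)
                    if "covariate" in table.columns
                    else ind.covariates,
                )


def simulate_disease(
    pedigree: Pedigree,
    truth: SimTruth,
    params: AssocParams,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Draw offspring affection statuses from the logistic disease model.

    The collapsed CNV coding C is computed from the true copy numbers
    across all markers; a standard-normal covariate X is drawn per
    offspring when ``gamma != 0``.  Returns a DataFrame with columns
    individual_id, family_id, C, affected (and covariate if used).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    off = truth.offspring()
    collapsed = (
        (off["true_cn"] != 2)
        .groupby([off["family_id"], off["individual_id"]], sort=True)
        .any()
        .astype(int)
        .rename("C")
        .reset_index()
    )
    fam_ids = sorted(pedigree.families)
    b = pd.Series(
        rng.normal(0.0, params.re_sd, size=len(fam_ids)) if params.re_sd > 0
        else np.zeros(len(fam_ids)),
        index=fam_ids,
    )
    eta = params.alpha + params.beta * collapsed["C"].to_numpy() + b.loc[
        collapsed["family_id"]
    ].to_numpy()
    out = collapsed
    if params.gamma != 0.0:
        x = rng.normal(size=len(out))
        eta = eta + params.gamma * x
        out["covariate"] = x
    p = 1.0 / (1.0 + np.exp(-eta))
    out["affected"] = (rng.random(len(out)) < p).astype(int)
    return out


def apply_two_stage(
    measurements: MeasurementSet,
    pedigree: Pedigree,
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
    extra_replicates: int = 4,
) -> MeasurementSet:
    """Simulate the two-stage replication design.

    Per marker, individuals whose stage-1 replicate average falls outside
    the cohort mean +/- 3 SD — together with every member of their family
    — receive ``extra_replicates`` additional simulated replicates (2
    become 6 under the default design).  A cohort SD of exactly zero
    escalates nobody.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    data = measurements.data
    truth_idx = truth.data.set_index(["individual_id", "marker_id"])
    new_rows = []
    for marker, sub in data.groupby("marker_id"):
        means = sub.groupby("individual_id")["value"].mean()
        if len(means) < 2:
            raise ValueError("two-stage rule needs at least 2 individuals")
        mu, sd = means.mean(), means.std(ddof=1)
        if sd == 0:
            continue
        outliers = means[(means < mu - 3 * sd) | (means > mu + 3 * sd)].index
        fams = {
            pedigree.individuals[iid].family_id for iid in outliers
        }
        escalated = [
            iid
            for fid in sorted(fams)
            for iid in sorted(pedigree.families[fid].members)
        ]
        start = int(sub["replicate"].max())
        for iid in escalated:
            cn = float(truth_idx.loc[(iid, marker), "true_cn"])
            vals = cn + rng.normal(0.0, config.meas_sd, size=extra_replicates)
            for k, v in enumerate(vals):
                new_rows.append((iid, marker, start + k + 1, v))
    if not new_rows:
        return MeasurementSet(data.copy())
    extra = pd.DataFrame(new_rows, columns=data.columns)
    return MeasurementSet(
        pd.concat([data, extra], ignore_index=True).sort_values(
            ["marker_id", "individual_id", "replicate"], kind="stable"
        ).reset_index(drop=True)
    )
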