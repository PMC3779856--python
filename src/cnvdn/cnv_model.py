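"""Generative model for replicated quantitative CNV data in nuclear families.

The latent state of a family at one marker consists of

* an unordered haplotype copy-number pair ``(a1, a2)`` per founder, with
  independent Poisson priors (truncated at ``max_allele`` and
  renormalized) on each haplotype value;
* per offspring, two fair-coin inheritance indicators ``k_f, k_m``
  choosing which parental haplotype is transmitted, and two rare
  Bernoulli mutation indicators ``theta_ins, theta_del`` for a de novo
  single-copy gain or loss.

An offspring's integer copy number is

    R = k_f*min(a_f) + (1-k_f)*max(a_f)
      + k_m*min(a_m) + (1-k_m)*max(a_m)
      + theta_ins - theta_del

and a founder's copy number is simply ``a1 + a2`` (no mutation in the
parental generation).  Each replicate measurement is Gaussian around the
latent integer CN with a shared standard deviation ``sigma``.

Because the state space of a nuclear family at a single marker is small
(unordered founder pairs x 16 offspring indicator combinations, with
offspring conditionally independent given the parents), the posterior can
be computed exactly by enumeration.  :func:`enumerate_family_posterior`
does this and serves both as a production inference engine for the
simulation studies and as the oracle against which the MCMC sampler is
validated.

Conventions: "P(gain)" in reports means P(theta_ins=1, theta_del=0); the
marginals P(theta_ins=1) and P(theta_del=1) are also exposed (the
simultaneous gain+loss state cancels in R and carries negligible
posterior mass at realistic priors).  Latent states whose raw R would be
negative are excluded (log-prior -inf) rather than clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import logsumexp
from scipy.stats import halfnorm, norm, poisson

from .pedigree_io import MeasurementSet, Pedigree

__all__ = [
    "ModelConfig",
    "LatentGenotype",
    "OffspringState",
    "FamilyData",
    "FamilyPosterior",
    "compose_offspring_cn",
    "log_likelihood_measurements",
    "log_prior_latent",
    "enumerate_family_posterior",
    "collapse_variants",
    "family_data_from",
    "pooled_replicate_sd",
]

_LOG_HALF = float(np.log(0.5))


@dataclass(frozen=True)
class ModelConfig:
    """Priors and supports for the hierarchical CNV model.

    Parameters
    ----------
    allele_prior_mean:
        Poisson mean for each founder haplotype copy number.  The default
        1.0 puts the expected diploid CN at 2.
    mutation_prior:
        Bernoulli prior for each of theta_ins and theta_del.  ``None``
        defers to the rule of thumb "no larger than the reciprocal of the
        number of genotyped offspring", resolved per dataset via
        :meth:`resolve_mutation_prior`.
    max_allele:
        Truncation bound for haplotype values in enumeration; copy
        numbers live on ``0 .. 2*max_allele + 1``.
    sigma_mode:
        How enumeration treats the measurement SD: ``"grid"``
        marginalizes over ``sigma_grid_size`` log-spaced values weighted
        by a Half-Normal(sigma_prior_scale) prior, ``"fixed"`` uses
        ``sigma_fixed``, ``"plugin"`` uses the pooled within-individual
        replicate SD of the family.
    """

    allele_prior_mean: float = 1.0
    mutation_prior: float | None = None
    max_allele: int = 4
    sigma_mode: str = "grid"
    sigma_fixed: float | None = None
    sigma_prior_scale: float = 1.0
    sigma_grid_size: int = 25
    sigma_grid_bounds: tuple[float, float] = (0.02, 1.0)
    markers: tuple[str, ...] = ()
    max_states: int = 1_000_000

    def __post_init__(self) -> None:
        if self.mutation_prior is not None and not (0.0 < self.mutation_prior <= 0.5):
            raise ValueError("mutation_prior must lie in (0, 0.5]")
        if self.max_allele < 2:
            raise ValueError("max_allele must be >= 2")
        if self.allele_prior_mean <= 0:
            raise ValueError("allele_prior_mean must be positive")
        if self.sigma_mode not in {"grid", "fixed", "plugin"}:
            raise ValueError(f"unknown sigma_mode {self.sigma_mode!r}")

    def resolve_mutation_prior(self, n_offspring: int) -> float:
        """Rule-of-thumb default: 1 / number of genotyped offspring."""
        if self.mutation_prior is not None:
            return self.mutation_prior
        return 1.0 / max(int(n_offspring), 2)

    @property
    def cn_grid(self) -> np.ndarray:
        return np.arange(2 * self.max_allele + 2)


@dataclass(frozen=True)
class OffspringState:
    k_f: int
    k_m: int
    theta_ins: int
    theta_del: int


@dataclass
class LatentGenotype:
    """A complete latent configuration for one family at one marker."""

    founder_alleles: dict[str, tuple[int, int]]
    offspring_states: dict[str, OffspringState] = field(default_factory=dict)


@dataclass
class FamilyData:
    """Replicate measurements for one nuclear family at one marker.

    A missing or untyped parent is represented by an empty replicate
    array; its haplotype pair remains latent with prior support only.
    """

    family_id: str
    father_reps: np.ndarray
    mother_reps: np.ndarray
    offspring: list[tuple[str, np.ndarray]]
    father_id: str | None = "father"
    mother_id: str | None = "mother"


@dataclass
class FamilyPosterior:
    """Exact (or marginalized-over-sigma) posterior for one family.

    ``cn_pmf`` maps member id to the posterior mass function over the
    integer CN grid; mutation probabilities are offspring-only.
    ``p_gain``/``p_loss`` exclude the simultaneous gain+loss state;
    ``p_ins``/``p_del`` are the raw indicator marginals.
    """

    family_id: str
    cn_grid: np.ndarray
    cn_pmf: dict[str, np.ndarray]
    mean_cn: dict[str, float]
    p_gain: dict[str, float]
    p_loss: dict[str, float]
    p_ins: dict[str, float]
    p_del: dict[str, float]
    p_cancel: dict[str, float]
    log_marginal: float
    sigma_posterior: tuple[np.ndarray, np.ndarray] | None = None


# ---------------------------------------------------------------------------
# elementary model pieces


def compose_offspring_cn(
    paternal_alleles: tuple[int, int],
    maternal_alleles: tuple[int, int],
    k_f: int,
    k_m: int,
    theta_ins: int,
    theta_del: int,
) -> int:
    """Offspring integer CN from parental haplotype pairs and indicators.

    ``k = 1`` transmits the smaller haplotype of the pair, ``k = 0`` the
    larger.  The result is floored at 0 (a deletion on a zero-copy
    transmission cannot go negative).
    """
    af = tuple(int(a) for a in paternal_alleles)
    am = tuple(int(a) for a in maternal_alleles)
    if min(af) < 0 or min(am) < 0:
        raise ValueError("haplotype copy numbers must be non-negative")
    r = (
        k_f * min(af)
        + (1 - k_f) * max(af)
        + k_m * min(am)
        + (1 - k_m) * max(am)
        + int(theta_ins)
        - int(theta_del)
    )
    return max(r, 0)


def log_likelihood_measurements(
    replicates: np.ndarray, cn: int, sigma: float
) -> float:
    """Gaussian log-likelihood of replicate measurements at integer CN.

    An empty replicate vector (untyped individual) contributes 0 by
    convention; ``sigma <= 0`` is an error.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(replicates, dtype=float)
    if x.size == 0:
        return 0.0
    return float(norm.logpdf(x, loc=cn, scale=sigma).sum())


def _trunc_poisson_logpmf(mu: float, a_max: int) -> np.ndarray:
    k = np.arange(a_max + 1)
    lp = poisson.logpmf(k, mu)
    return lp - logsumexp(lp)


def log_prior_latent(genotype: LatentGenotype, config: ModelConfig) -> float:
    """Joint log-prior of a latent family configuration.

    Founder haplotypes: independent truncated Poisson; inheritance
    indicators: Bernoulli(0.5) each; mutation indicators:
    Bernoulli(mutation_prior) each.  Requires ``mutation_prior`` to be
    set (the rule-of-thumb default is dataset-dependent).
    """
    mut = config.mutation_prior
    if mut is None:
        raise ValueError("mutation_prior unresolved; call resolve_mutation_prior")
    allele_lp = _trunc_poisson_logpmf(config.allele_prior_mean, config.max_allele)
    total = 0.0
    for a1, a2 in genotype.founder_alleles.values():
        for a in (a1, a2):
            if not 0 <= a <= config.max_allele:
                raise ValueError(f"allele {a} outside 0..{config.max_allele}")
            total += float(allele_lp[a])
    lmut1 = float(np.log(mut))
    lmut0 = float(np.log1p(-mut))
    for st in genotype.offspring_states.values():
        total += 2 * _LOG_HALF
        total += lmut1 if st.theta_ins else lmut0
        total += lmut1 if st.theta_del else lmut0
    return total


def collapse_variants(cn_by_marker: np.ndarray) -> int:
    """Binary collapsed coding over L markers: 0 iff every CN equals 2."""
    cns = np.asarray(cn_by_marker)
    if cns.size < 1:
        raise ValueError("need at least one marker")
    return int(not np.all(cns == 2))


# ---------------------------------------------------------------------------
# enumeration tables


@dataclass(frozen=True)
class EnumTables:
    """Precomputed enumeration tables for a given (max_allele, Poisson mean).

    Founder pairs are unordered (min/max composition makes within-parent
    order irrelevant); distinct-valued pairs carry a multiplicity-2 prior
    weight.
    """

    lo: np.ndarray          # (m,)
    hi: np.ndarray          # (m,)
    s: np.ndarray           # (m,) pair sum = founder CN
    pair_logw: np.ndarray   # (m,)
    kf: np.ndarray          # (16,)
    km: np.ndarray
    ti: np.ndarray
    td: np.ndarray
    cn: np.ndarray          # (m, m, 16) offspring CN per (father pair, mother pair, combo)
    valid: np.ndarray       # (m, m, 16) False where raw CN would be negative
    n_grid: int

    @property
    def n_pairs(self) -> int:
        return len(self.lo)

    def combo_logw(self, p_ins: float, p_del: float) -> np.ndarray:
        """Log-prior of each (k_f, k_m, theta_ins, theta_del) combination."""
        return (
            2 * _LOG_HALF
            + np.where(self.ti == 1, np.log(p_ins), np.log1p(-p_ins))
            + np.where(self.td == 1, np.log(p_del), np.log1p(-p_del))
        )


@lru_cache(maxsize=16)
def build_tables(max_allele: int, allele_prior_mean: float) -> EnumTables:
    allele_lp = _trunc_poisson_logpmf(allele_prior_mean, max_allele)
    lo_l, hi_l, w_l = [], [], []
    for a1 in range(max_allele + 1):
        for a2 in range(a1, max_allele + 1):
            lo_l.append(a1)
            hi_l.append(a2)
            w = allele_lp[a1] + allele_lp[a2]
            if a1 != a2:
                w += np.log(2.0)  # two ordered pairs collapse onto one unordered
            w_l.append(w)
    lo = np.array(lo_l)
    hi = np.array(hi_l)
    pair_logw = np.array(w_l)

    idx = np.arange(16)
    kf, km = idx & 1, (idx >> 1) & 1
    ti, td = (idx >> 2) & 1, (idx >> 3) & 1
    # k = 1 transmits the smaller haplotype
    tf = np.where(kf[None, :] == 1, lo[:, None], hi[:, None])  # (m, 16)
    tm = np.where(km[None, :] == 1, lo[:, None], hi[:, None])
    raw = tf[:, None, :] + tm[None, :, :] + ti[None, None, :] - td[None, None, :]
    valid = raw >= 0
    cn = np.where(valid, raw, 0)
    return EnumTables(
        lo=lo, hi=hi, s=lo + hi, pair_logw=pair_logw,
        kf=kf, km=km, ti=ti, td=td,
        cn=cn, valid=valid, n_grid=2 * max_allele + 2,
    )


# ---------------------------------------------------------------------------
# batched exact posterior (fixed sigma)


def posterior_from_logliks(
    parent_ll: np.ndarray,
    kid_ll: np.ndarray,
    kid_mask: np.ndarray,
    tables: EnumTables,
    p_ins: float,
    p_del: float,
) -> dict[str, np.ndarray]:
    """Exact family posteriors from per-individual CN log-likelihood tables.

    Parameters
    ----------
    parent_ll:
        ``(F, 2, G)`` log-likelihood of each parent's replicates at every
        CN grid value (zeros for missing/untyped parents).
    kid_ll:
        ``(F, J, G)`` likewise for offspring slots.
    kid_mask:
        ``(F, J)`` boolean; False marks padding slots in ragged families.

    Returns arrays keyed ``log_z``, ``p_ins``, ``p_del``, ``p_gain``,
    ``p_loss``, ``p_cancel`` (``(F, J)``), ``kid_pmf`` (``(F, J, G)``)
    and ``parent_pmf`` (``(F, 2, G)``).
    """
    F, J, G = kid_ll.shape
    m = tables.n_pairs
    clw = tables.combo_logw(p_ins, p_del)

    with np.errstate(invalid="ignore"):
        T = kid_ll[:, :, tables.cn] + clw  # (F, J, m, m, 16)
        T = np.where(tables.valid, T, -np.inf)
        kid_term = logsumexp(T, axis=-1)  # (F, J, m, m)
        cond = np.exp(T - kid_term[..., None])
    kid_term = np.where(kid_mask[:, :, None, None], kid_term, 0.0)

    fa = parent_ll[:, 0, :][:, tables.s]  # (F, m)
    mo = parent_ll[:, 1, :][:, tables.s]
    joint = (
        tables.pair_logw[None, :, None]
        + tables.pair_logw[None, None, :]
        + fa[:, :, None]
        + mo[:, None, :]
        + kid_term.sum(axis=1)
    )
    log_z = logsumexp(joint, axis=(1, 2))
    W = np.exp(joint - log_z[:, None, None])  # (F, m, m)

    marg = np.einsum("fab,fjabc->fjc", W, cond)  # (F, J, 16) combo marginals
    p_ins_m = marg[:, :, tables.ti == 1].sum(axis=-1)
    p_del_m = marg[:, :, tables.td == 1].sum(axis=-1)
    p_gain = marg[:, :, (tables.ti == 1) & (tables.td == 0)].sum(axis=-1)
    p_loss = marg[:, :, (tables.td == 1) & (tables.ti == 0)].sum(axis=-1)
    p_cancel = marg[:, :, (tables.ti == 1) & (tables.td == 1)].sum(axis=-1)

    onehot = (tables.cn[..., None] == np.arange(G)) & tables.valid[..., None]
    kid_pmf = np.einsum("fab,fjabc,abcg->fjg", W, cond, onehot.astype(float))

    onehot_s = (tables.s[:, None] == np.arange(G)).astype(float)  # (m, G)
    parent_pmf = np.stack(
        [W.sum(axis=2) @ onehot_s, W.sum(axis=1) @ onehot_s], axis=1
    )
    return {
        "log_z": log_z,
        "p_ins": p_ins_m,
        "p_del": p_del_m,
        "p_gain": p_gain,
        "p_loss": p_loss,
        "p_cancel": p_cancel,
        "kid_pmf": kid_pmf,
        "parent_pmf": parent_pmf,
    }


def loglik_table(reps: np.ndarray, sigma: float, n_grid: int) -> np.ndarray:
    """Log-likelihood of a replicate vector at every grid CN (full density)."""
    x = np.asarray(reps, dtype=float)
    if x.size == 0:
        return np.zeros(n_grid)
    grid = np.arange(n_grid)
    sse = ((x[:, None] - grid[None, :]) ** 2).sum(axis=0)
    return -sse / (2 * sigma**2) - x.size * np.log(sigma * np.sqrt(2 * np.pi))


def pooled_replicate_sd(rep_arrays: list[np.ndarray]) -> float:
    """Pooled within-individual replicate SD (plug-in sigma estimate)."""
    num = 0.0
    dof = 0
    for reps in rep_arrays:
        x = np.asarray(reps, dtype=float)
        if x.size >= 2:
            num += float(((x - x.mean()) ** 2).sum())
            dof += x.size - 1
    if dof == 0:
        raise ValueError("no individual has >= 2 replicates; cannot pool SD")
    return float(np.sqrt(num / dof))


def sigma_grid(config: ModelConfig) -> tuple[np.ndarray, np.ndarray]:
    """Log-spaced sigma grid with normalized Half-Normal prior weights."""
    lo, hi = config.sigma_grid_bounds
    grid = np.geomspace(lo, hi, config.sigma_grid_size)
    logw = halfnorm.logpdf(grid, scale=config.sigma_prior_scale) + np.log(grid)
    return grid, logw - logsumexp(logw)


def enumerate_family_posterior(
    family: FamilyData,
    config: ModelConfig,
    sigma: float | np.ndarray | None = None,
) -> FamilyPosterior:
    """Exact posterior for one nuclear family at one marker.

    ``sigma`` overrides the config: a scalar fixes the measurement SD, an
    array marginalizes over that grid with the Half-Normal prior weights.
    With ``sigma=None`` the config's ``sigma_mode`` applies.
    """
    tables = build_tables(config.max_allele, config.allele_prior_mean)
    if tables.n_pairs**2 > config.max_states:
        raise ValueError(
            f"state space {tables.n_pairs**2} exceeds max_states={config.max_states}"
        )
    mut = config.resolve_mutation_prior(len(family.offspring))

    if sigma is None:
        if config.sigma_mode == "fixed":
            if config.sigma_fixed is None:
                raise ValueError("sigma_mode='fixed' requires sigma_fixed")
            sigmas, sig_logw = np.array([config.sigma_fixed]), np.array([0.0])
        elif config.sigma_mode == "plugin":
            reps = [family.father_reps, family.mother_reps] + [
                r for _, r in family.offspring
            ]
            sigmas, sig_logw = np.array([pooled_replicate_sd(reps)]), np.array([0.0])
        else:
            sigmas, sig_logw = sigma_grid(config)
    elif np.ndim(sigma) == 0:
        sigmas, sig_logw = np.array([float(sigma)]), np.array([0.0])
    else:
        sigmas = np.asarray(sigma, dtype=float)
        lw = halfnorm.logpdf(sigmas, scale=config.sigma_prior_scale) + np.log(sigmas)
        sig_logw = lw - logsumexp(lw)

    G = tables.n_grid
    J = max(len(family.offspring), 1)
    results = []
    for s in sigmas:
        if s <= 0:
            raise ValueError("sigma values must be positive")
        par_ll = np.stack(
            [loglik_table(family.father_reps, s, G), loglik_table(family.mother_reps, s, G)]
        )[None]
        kid_ll = np.zeros((1, J, G))
        kid_mask = np.zeros((1, J), dtype=bool)
        for j, (_, reps) in enumerate(family.offspring):
            kid_ll[0, j] = loglik_table(reps, s, G)
            kid_mask[0, j] = True
        results.append(
            posterior_from_logliks(par_ll, kid_ll, kid_mask, tables, mut, mut)
        )

    log_z_s = np.array([r["log_z"][0] for r in results]) + sig_logw
    log_marginal = float(logsumexp(log_z_s))
    w_s = np.exp(log_z_s - log_marginal)

    def mix(key: str) -> np.ndarray:
        return np.tensordot(w_s, np.stack([r[key][0] for r in results]), axes=(0, 0))

    kid_pmf = mix("kid_pmf")
    parent_pmf = mix("parent_pmf")
    p_ins, p_del = mix("p_ins"), mix("p_del")
    p_gain, p_loss, p_cancel = mix("p_gain"), mix("p_loss"), mix("p_cancel")

    grid = np.arange(G)
    cn_pmf: dict[str, np.ndarray] = {}
    mean_cn: dict[str, float] = {}
    for idx, pid in enumerate((family.father_id, family.mother_id)):
        if pid is not None:
            cn_pmf[pid] = parent_pmf[idx]
            mean_cn[pid] = float(parent_pmf[idx] @ grid)
    d_gain, d_loss, d_ins, d_del, d_cancel = {}, {}, {}, {}, {}
    for j, (oid, _) in enumerate(family.offspring):
        cn_pmf[oid] = kid_pmf[j]
        mean_cn[oid] = float(kid_pmf[j] @ grid)
        d_gain[oid] = float(p_gain[j])
        d_loss[oid] = float(p_loss[j])
        d_ins[oid] = float(p_ins[j])
        d_del[oid] = float(p_del[j])
        d_cancel[oid] = float(p_cancel[j])

    return FamilyPosterior(
        family_id=family.family_id,
        cn_grid=grid,
        cn_pmf=cn_pmf,
        mean_cn=mean_cn,
        p_gain=d_gain,
        p_loss=d_loss,
        p_ins=d_ins,
        p_del=d_del,
        p_cancel=d_cancel,
        log_marginal=log_marginal,
        sigma_posterior=(sigmas, w_s) if len(sigmas) > 1 else None,
    )


# ---------------------------------------------------------------------------
# assembling FamilyData from the IO containers


def family_data_from(
    pedigree: Pedigree,
    measurements: MeasurementSet,
    family_id: str,
    marker_id: str,
) -> FamilyData:
    """Collect one family's replicates at one marker into a FamilyData.

    The founder referenced as father (mother) of the offspring supplies
    the paternal (maternal) replicates; a parent that is unrecruited or
    untyped contributes an empty replicate vector.
    """
    fam = pedigree.families[family_id]
    offspring = sorted(fam.offspring, key=lambda m: m.individual_id)
    father_id = next((o.father_id for o in offspring if o.father_id), None)
    mother_id = next((o.mother_id for o in offspring if o.mother_id), None)

    def reps(iid: str | None) -> np.ndarray:
        if iid is None:
            return np.empty(0)
        return measurements.replicates(iid, marker_id)

    return FamilyData(
        family_id=family_id,
        father_reps=reps(father_id),
        mother_reps=reps(mother_id),
        offspring=[(o.individual_id, reps(o.individual_id)) for o in offspring],
        father_id=father_id,
        mother_id=mother_id,
    )
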