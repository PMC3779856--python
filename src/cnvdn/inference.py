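"""Metropolis-within-Gibbs sampling for the joint CNV / association model.

Discrete latents (founder haplotype pairs, per-offspring inheritance and
mutation indicators) are updated by *enumerated* full conditionals: at
each step the complete conditional distribution over the small discrete
support is computed and sampled exactly.  This removes the mixing
pathologies that plague single-bit-flip proposals on rare mutation
indicators.  Continuous parameters (the measurement SD per marker and,
in the association model, the logistic coefficients, family random
effects and their SD) move by random-walk Metropolis.

Updates are vectorized across families in a canonical order (families
sorted by ID, offspring sorted by ID within family), so permuting the
input order changes nothing, even at a fixed seed.

Default priors (the source model left these open): regression
coefficients Normal(0, 10^2); measurement SD Half-Normal(0, 1);
random-effect SD Half-Normal(0, 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cnv_model import EnumTables, ModelConfig, build_tables
from .pedigree_io import MeasurementSet, Pedigree
from .results import AssociationFit, PosteriorSummary

__all__ = [
    "MCMCConfig",
    "PosteriorDraws",
    "run_detection_mcmc",
    "run_association_mcmc",
    "summarize_mutations",
    "split_rhat",
]

DEFAULT_THRESHOLDS = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass(frozen=True)
class MCMCConfig:
    n_burnin: int = 50_000
    n_iter: int = 50_000
    thin: int = 10
    chains: int = 2
    seed: int | None = None
    sigma_fixed: float | None = None  # freeze the measurement SD (no sigma updates)
    latent_update_every: int = 1  # refresh discrete latents every k-th sweep
    coef_updates_per_sweep: int = 3  # extra Metropolis cycles on (alpha, beta)
    coef_prior_sd: float = 10.0
    sigma_prior_scale: float = 1.0
    re_sd_prior_scale: float = 1.0
    step_sigma: float = 0.15      # RW scale on log sigma
    step_coef: float = 0.25
    step_re: float = 0.6
    step_tau: float = 0.4

    def __post_init__(self) -> None:
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_iter < self.thin:
            raise ValueError("n_iter must be >= thin")
        if self.chains < 1:
            raise ValueError("chains must be >= 1")


@dataclass
class PosteriorDraws:
    """Retained MCMC output: per-individual summaries plus parameter draws."""

    individuals: pd.DataFrame
    params: dict[str, np.ndarray]  # name -> (chains, n_retained)
    rhat: dict[str, float] = field(default_factory=dict)
    n_retained: int = 0

    def param_summary(self) -> pd.DataFrame:
        rows = []
        for name, d in self.params.items():
            flat = d.ravel()
            rows.append(
                (name, flat.mean(), flat.std(ddof=1), 100.0 * np.mean(flat > 0))
            )
        return pd.DataFrame(rows, columns=["term", "mean", "sd", "p_gt0_pct"])


def split_rhat(draws: np.ndarray) -> float:
    """Split-R-hat over an array of draws shaped (chains, n)."""
    d = np.atleast_2d(np.asarray(draws, dtype=float))
    c, n = d.shape
    half = n // 2
    if half < 2:
        return float("nan")
    x = d[:, : 2 * half].reshape(c * 2, half)
    w = x.var(axis=1, ddof=1).mean()
    b = half * x.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0
    return float(np.sqrt(((half - 1) / half * w + b / half) / w))


# ---------------------------------------------------------------------------
# data preparation


@dataclass
class _FamilyLayout:
    family_ids: list[str]
    father_ids: list[str | None]
    mother_ids: list[str | None]
    kid_ids: list[list[str]]
    j_max: int

    @property
    def n_families(self) -> int:
        return len(self.family_ids)


def _layout(pedigree: Pedigree) -> _FamilyLayout:
    fids = sorted(pedigree.families)
    fathers, mothers, kids = [], [], []
    for fid in fids:
        fam = pedigree.families[fid]
        off = sorted(fam.offspring, key=lambda m: m.individual_id)
        fathers.append(next((o.father_id for o in off if o.father_id), None))
        mothers.append(next((o.mother_id for o in off if o.mother_id), None))
        kids.append([o.individual_id for o in off])
    j_max = max((len(k) for k in kids), default=1) or 1
    return _FamilyLayout(fids, fathers, mothers, kids, j_max)


def _replicate_map(ms: MeasurementSet) -> dict[tuple[str, str], np.ndarray]:
    """(individual, marker) -> replicate array, built in one pass."""
    if ms.data.empty:
        return {}
    return {
        key: grp["value"].to_numpy(dtype=float)
        for key, grp in ms.data.groupby(["individual_id", "marker_id"], sort=False)
    }


def _sse_tables(
    layout: _FamilyLayout,
    reps: dict[tuple[str, str], np.ndarray],
    marker: str,
    n_grid: int,
) -> dict[str, np.ndarray]:
    """Sufficient statistics per individual: sum of squared residuals at
    each grid CN, and replicate counts."""
    F, J = layout.n_families, layout.j_max
    grid = np.arange(n_grid)
    par_sse = np.zeros((F, 2, n_grid))
    par_n = np.zeros((F, 2), dtype=int)
    kid_sse = np.zeros((F, J, n_grid))
    kid_n = np.zeros((F, J), dtype=int)
    kid_mask = np.zeros((F, J), dtype=bool)

    def sse(iid: str | None) -> tuple[np.ndarray, int]:
        x = reps.get((iid, marker)) if iid is not None else None
        if x is None or x.size == 0:
            return np.zeros(n_grid), 0
        return ((x[:, None] - grid[None, :]) ** 2).sum(axis=0), x.size

    for i in range(F):
        par_sse[i, 0], par_n[i, 0] = sse(layout.father_ids[i])
        par_sse[i, 1], par_n[i, 1] = sse(layout.mother_ids[i])
        for j, kid in enumerate(layout.kid_ids[i]):
            kid_sse[i, j], kid_n[i, j] = sse(kid)
            kid_mask[i, j] = True
    return {
        "par_sse": par_sse, "par_n": par_n,
        "kid_sse": kid_sse, "kid_n": kid_n, "kid_mask": kid_mask,
    }


# ---------------------------------------------------------------------------
# the sampler


def _gumbel_argmax(logits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample one category per row of unnormalized log-probabilities."""
    g = rng.gumbel(size=logits.shape)
    return np.argmax(np.where(np.isneginf(logits), -np.inf, logits) + g, axis=-1)


def _logsumexp_last(x: np.ndarray) -> np.ndarray:
    """logsumexp over the last axis, tolerant of -inf entries."""
    m = np.max(x, axis=-1)
    safe = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(invalid="ignore"):
        out = safe + np.log(np.exp(x - safe[..., None]).sum(axis=-1))
    return np.where(np.isfinite(m), out, -np.inf)


# plain-numpy log-densities: scipy.stats call overhead dominates tight
# Metropolis loops, so the few densities the sampler needs are inlined.
_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _norm_logpdf(x, sd):
    return -0.5 * (np.asarray(x) / sd) ** 2 - np.log(sd) - _LOG_SQRT_2PI


def _halfnorm_logpdf(x, scale):
    return np.log(2.0) + _norm_logpdf(x, scale)


class _GibbsSampler:
    """One-chain state and sweep logic; vectorized across families."""

    def __init__(
        self,
        layout: _FamilyLayout,
        marker_stats: dict[str, dict[str, np.ndarray]],
        tables: EnumTables,
        mutation_prior: float,
        cfg: MCMCConfig,
        assoc: dict | None = None,
    ):
        self.layout = layout
        self.markers = sorted(marker_stats)
        self.stats = marker_stats
        self.tables = tables
        self.cfg = cfg
        self.assoc = assoc
        self.F = layout.n_families
        self.J = layout.j_max
        self.G = tables.n_grid
        self.clw = tables.combo_logw(mutation_prior, mutation_prior)
        self._fidx = np.arange(self.F)

    # -- initialization ----------------------------------------------------

    def init_state(self) -> dict:
        t = self.tables
        state: dict = {"pf": {}, "pm": {}, "combo": {}, "sigma": {}}
        for mk in self.markers:
            st = self.stats[mk]
            pf = np.empty(self.F, dtype=int)
            pm = np.empty(self.F, dtype=int)
            for col, out in ((0, pf), (1, pm)):
                n = st["par_n"][:, col]
                sse = st["par_sse"][:, col, :]
                mean_cn = np.where(n > 0, np.argmin(sse, axis=1), 2)
                for i in range(self.F):
                    cand = np.flatnonzero(t.s == mean_cn[i])
                    if cand.size == 0:
                        cand = np.array([int(np.argmin(np.abs(t.s - mean_cn[i])))])
                    out[i] = cand[np.argmax(t.pair_logw[cand])]
            state["pf"][mk] = pf
            state["pm"][mk] = pm
            state["combo"][mk] = np.zeros((self.F, self.J), dtype=int)
            state["sigma"][mk] = (
                0.2 if self.cfg.sigma_fixed is None else float(self.cfg.sigma_fixed)
            )
        if self.assoc is not None:
            y = self.assoc["y"]
            obs = np.isfinite(y)
            rate = float(y[obs].mean()) if obs.any() else 0.5
            rate = min(max(rate, 0.05), 0.95)
            state["alpha"] = float(np.log(rate / (1 - rate)))
            state["beta"] = 0.0
            state["gamma"] = np.zeros(self.assoc["X"].shape[2])
            state["b"] = np.zeros(self.F)
            state["tau"] = 0.5 * self.cfg.re_sd_prior_scale
        return state

    # -- likelihood helpers ------------------------------------------------

    def _kid_cn(self, state: dict, mk: str) -> np.ndarray:
        t = self.tables
        pf, pm, combo = state["pf"][mk], state["pm"][mk], state["combo"][mk]
        return t.cn[pf, pm, :][self._fidx[:, None], combo]  # (F, J)

    def _collapsed_other(self, state: dict, mk: str) -> np.ndarray:
        """Product over all markers except mk of I{CN == 2}, per kid."""
        prod = np.ones((self.F, self.J))
        for other in self.markers:
            if other == mk:
                continue
            prod *= (self._kid_cn(state, other) == 2).astype(float)
        return prod

    def _collapsed_C(self, state: dict) -> np.ndarray:
        C = np.ones((self.F, self.J))
        for mk in self.markers:
            C *= (self._kid_cn(state, mk) == 2).astype(float)
        return 1.0 - C

    def _logistic_tables(self, state: dict) -> dict:
        """Per-kid logistic log-likelihood at C = 0 and the C = 1 increment.

        The collapsed coding is binary, so during the latent sweeps the
        phenotype term only ever takes two values per offspring; the
        latent updates then reduce to a multiply-add."""
        a = self.assoc
        base = state["alpha"] + a["X"] @ state["gamma"] + state["b"][:, None]
        ll = []
        for c in (0.0, 1.0):
            eta = base + state["beta"] * c
            ll.append(np.where(a["mask"], a["y"] * eta - np.logaddexp(0.0, eta), 0.0))
        return {"ll0": ll[0], "d": ll[1] - ll[0]}

    # -- sweeps ------------------------------------------------------------

    def sweep(self, state: dict, rng: np.random.Generator, it: int = 0) -> None:
        if it % self.cfg.latent_update_every == 0:
            lly = self._logistic_tables(state) if self.assoc is not None else None
            for mk in self.markers:
                self._update_parents(state, mk, rng, lly)
                self._update_kids(state, mk, rng, lly)
                self._update_sigma(state, mk, rng)
        if self.assoc is not None:
            self._update_assoc(state, rng)

    def _kid_value_tables(self, state: dict, mk: str, lly) -> list[np.ndarray]:
        """Per offspring: exp of the (row-max-shifted) log-likelihood of its
        replicates at every grid CN, padded with a zero column at index 0
        so that excluded states (raw CN -1) pick up weight zero."""
        st = self.stats[mk]
        sig2 = 2.0 * state["sigma"][mk] ** 2
        if lly is not None:
            other_prod = self._collapsed_other(state, mk)
            is2 = (np.arange(self.G)[None, :] == 2).astype(float)
        out = []
        for j in range(self.J):
            E = -st["kid_sse"][:, j, :] / sig2
            if lly is not None:
                c_of_g = 1.0 - is2 * other_prod[:, j][:, None]
                E = E + lly["ll0"][:, j][:, None] + lly["d"][:, j][:, None] * c_of_g
            E = E - E.max(axis=1, keepdims=True)  # per-row shift: cancels in sampling
            vp = np.zeros((self.F, self.G + 1))
            vp[:, 1:] = np.exp(E)
            out.append(vp)
        return out

    def _update_parents(self, state: dict, mk: str, rng, lly=None) -> None:
        """Partially collapsed update: each parent's pair is drawn with the
        offspring indicator combinations summed out (they are resampled in
        the kid sweep right after), which bridges the strongly coupled
        (pair, combo) modes that plague uncollapsed single-site updates.

        The sum over a child's 16 indicator combinations factorizes: given
        the co-parent's transmitted value t and mutation shift d, the child
        likelihood only depends on v + t + d where v is the candidate
        parent's transmitted value, so the collapse reduces to 8 weighted
        gathers on the padded value table followed by a 2-term average over
        the candidate pair's own transmissions."""
        t, st = self.tables, self.stats[mk]
        sig2 = 2.0 * state["sigma"][mk] ** 2
        # mutation weights recovered from the combo prior table
        log_half2 = 2 * np.log(0.5)
        w_no = float(np.exp(self.clw[0] - log_half2))
        w_ins = float(np.exp(self.clw[4] - log_half2))
        w_del = float(np.exp(self.clw[8] - log_half2))
        w_both = float(np.exp(self.clw[12] - log_half2))
        shifts = ((w_no + w_both, 0), (w_ins, 1), (w_del, -1))
        vtables = self._kid_value_tables(state, mk, lly)
        A1 = t.lo.max() + 1  # haplotype values 0..max_allele
        vgrid = np.arange(A1)
        for which in (0, 1):  # father first, then mother given new father
            other = state["pm"][mk] if which == 0 else state["pf"][mk]
            own_sse = st["par_sse"][:, which, :]
            logits = t.pair_logw[None, :] - own_sse[:, t.s] / sig2  # (F, m)
            t_lo, t_hi = t.lo[other], t.hi[other]  # co-parent transmissions (F,)
            for j in range(self.J):
                vp = vtables[j]
                H = np.zeros((self.F, A1))
                for tr in (t_lo, t_hi):  # co-parent k choice, weight 1/2 each
                    base = vgrid[None, :] + tr[:, None] + 1  # +1 = pad offset
                    for w, d in shifts:
                        H += (0.5 * w) * vp[self._fidx[:, None], base + d]
                with np.errstate(divide="ignore"):
                    kid_term = np.log(0.5 * (H[:, t.lo] + H[:, t.hi]))  # (F, m)
                mask = st["kid_mask"][:, j]
                logits += np.where(mask[:, None], kid_term, 0.0)
            new = _gumbel_argmax(logits, rng)
            if which == 0:
                state["pf"][mk] = new
            else:
                state["pm"][mk] = new

    def _update_kids(self, state: dict, mk: str, rng, lly=None) -> None:
        t, st = self.tables, self.stats[mk]
        sig2 = 2.0 * state["sigma"][mk] ** 2
        pf, pm = state["pf"][mk], state["pm"][mk]
        cn_c = t.cn[pf, pm, :]        # (F, 16)
        valid_c = t.valid[pf, pm, :]
        if lly is not None:
            other = self._collapsed_other(state, mk)  # (F, J)
        for j in range(self.J):
            ll = -np.take_along_axis(st["kid_sse"][:, j, :], cn_c, axis=1) / sig2
            logits = self.clw[None, :] + np.where(valid_c, ll, -np.inf)
            if lly is not None:
                C_cand = 1.0 - (cn_c == 2) * other[:, j][:, None]  # (F, 16)
                logits = logits + lly["d"][:, j][:, None] * C_cand
            new = _gumbel_argmax(logits, rng)
            mask = st["kid_mask"][:, j]
            state["combo"][mk][:, j] = np.where(mask, new, 0)

    def _update_sigma(self, state: dict, mk: str, rng) -> None:
        if self.cfg.sigma_fixed is not None:
            return
        st = self.stats[mk]
        t = self.tables
        pf, pm = state["pf"][mk], state["pm"][mk]
        sse = (
            st["par_sse"][self._fidx, 0, t.s[pf]].sum()
            + st["par_sse"][self._fidx, 1, t.s[pm]].sum()
        )
        kid_cn = self._kid_cn(state, mk)
        sse += np.take_along_axis(st["kid_sse"], kid_cn[..., None], axis=2)[
            ..., 0
        ][st["kid_mask"]].sum()
        n_tot = st["par_n"].sum() + st["kid_n"].sum()

        def log_target(phi: float) -> float:
            s = np.exp(phi)
            return (
                -n_tot * phi
                - sse / (2 * s**2)
                + float(_halfnorm_logpdf(s, self.cfg.sigma_prior_scale))
                + phi
            )

        phi = np.log(state["sigma"][mk])
        prop = phi + self.cfg.step_sigma * rng.standard_normal()
        if np.log(rng.random()) < log_target(prop) - log_target(phi):
            state["sigma"][mk] = float(np.exp(prop))

    def _update_assoc(self, state: dict, rng) -> None:
        """Metropolis updates of the logistic block at fixed latent CNs."""
        cfg = self.cfg
        a = self.assoc
        C = self._collapsed_C(state)  # fixed during this block
        y, mask, X = a["y"], a["mask"], a["X"]

        def ll_terms(alpha, beta, gamma, b) -> np.ndarray:
            eta = alpha + beta * C + X @ gamma + b[:, None]
            return np.where(mask, y * eta - np.logaddexp(0.0, eta), 0.0)

        cur = ll_terms(state["alpha"], state["beta"], state["gamma"], state["b"])
        cur_ll = float(cur.sum())
        # fixed effects, one at a time; (alpha, beta) are posterior-correlated
        # so their cycle is repeated a few times per sweep
        for _ in range(max(cfg.coef_updates_per_sweep, 1)):
            for name in ("alpha", "beta"):
                cand = state[name] + cfg.step_coef * rng.standard_normal()
                trial = {
                    "alpha": state["alpha"], "beta": state["beta"],
                    "gamma": state["gamma"], "b": state["b"], name: cand,
                }
                new_ll = float(ll_terms(**trial).sum())
                dprior = float(
                    _norm_logpdf(cand, cfg.coef_prior_sd)
                    - _norm_logpdf(state[name], cfg.coef_prior_sd)
                )
                if np.log(rng.random()) < new_ll - cur_ll + dprior:
                    state[name] = cand
                    cur_ll = new_ll
        for k in range(len(state["gamma"])):
            g = state["gamma"].copy()
            g[k] += cfg.step_coef * rng.standard_normal()
            new_ll = float(
                ll_terms(state["alpha"], state["beta"], g, state["b"]).sum()
            )
            dprior = float(
                _norm_logpdf(g[k], cfg.coef_prior_sd)
                - _norm_logpdf(state["gamma"][k], cfg.coef_prior_sd)
            )
            if np.log(rng.random()) < new_ll - cur_ll + dprior:
                state["gamma"] = g
                cur_ll = new_ll
        # family random effects, vectorized accept/reject
        tau = max(state["tau"], 1e-6)
        b_prop = state["b"] + cfg.step_re * rng.standard_normal(self.F)
        ll_old = ll_terms(
            state["alpha"], state["beta"], state["gamma"], state["b"]
        ).sum(axis=1)
        ll_new = ll_terms(
            state["alpha"], state["beta"], state["gamma"], b_prop
        ).sum(axis=1)
        dprior = _norm_logpdf(b_prop, tau) - _norm_logpdf(state["b"], tau)
        accept = np.log(rng.random(self.F)) < ll_new - ll_old + dprior
        state["b"] = np.where(accept, b_prop, state["b"])
        # random-effect SD (log-scale random walk)
        phi = np.log(max(state["tau"], 1e-6))
        prop_phi = phi + cfg.step_tau * rng.standard_normal()

        def tau_target(p: float) -> float:
            s = np.exp(p)
            return float(
                _norm_logpdf(state["b"], s).sum()
                + _halfnorm_logpdf(s, cfg.re_sd_prior_scale)
                + p
            )

        if np.log(rng.random()) < tau_target(prop_phi) - tau_target(phi):
            state["tau"] = float(np.exp(prop_phi))
        # joint scale move on (b, tau): decorrelates the funnel between the
        # random effects and their SD, which single-site updates walk slowly
        c = float(np.exp(0.5 * cfg.step_tau * rng.standard_normal()))
        b_s, tau_s = state["b"] * c, max(state["tau"], 1e-6) * c
        ll_old = float(
            ll_terms(state["alpha"], state["beta"], state["gamma"], state["b"]).sum()
        )
        ll_new = float(
            ll_terms(state["alpha"], state["beta"], state["gamma"], b_s).sum()
        )
        dprior = float(
            _norm_logpdf(b_s, tau_s).sum()
            - _norm_logpdf(state["b"], max(state["tau"], 1e-6)).sum()
            + _halfnorm_logpdf(tau_s, cfg.re_sd_prior_scale)
            - _halfnorm_logpdf(max(state["tau"], 1e-6), cfg.re_sd_prior_scale)
        )
        if np.log(rng.random()) < ll_new - ll_old + dprior + (self.F + 1) * np.log(c):
            state["b"] = b_s
            state["tau"] = tau_s

    # -- running -----------------------------------------------------------

    def run_chain(self, seed_key: tuple[int, ...]) -> dict:
        cfg = self.cfg
        rng = np.random.default_rng(seed_key)
        state = self.init_state()
        t = self.tables
        n_keep = cfg.n_iter // cfg.thin
        acc = {
            mk: {
                "gain": np.zeros((self.F, self.J)),
                "loss": np.zeros((self.F, self.J)),
                "ins": np.zeros((self.F, self.J)),
                "del": np.zeros((self.F, self.J)),
                "kid_cn": np.zeros((self.F, self.J, self.G)),
                "par_cn": np.zeros((self.F, 2, self.G)),
            }
            for mk in self.markers
        }
        draws: dict[str, list[float]] = {f"sigma_{mk}": [] for mk in self.markers}
        if self.assoc is not None:
            for nm in ["alpha", "beta", "tau"]:
                draws[nm] = []
            for k in range(len(state["gamma"])):
                draws[f"gamma_{k}"] = []

        for it in range(cfg.n_burnin + cfg.n_iter):
            self.sweep(state, rng, it)
            if it < cfg.n_burnin or (it - cfg.n_burnin) % cfg.thin != 0:
                continue
            for mk in self.markers:
                combo = state["combo"][mk]
                ti = t.ti[combo]
                td = t.td[combo]
                a = acc[mk]
                a["gain"] += (ti == 1) & (td == 0)
                a["loss"] += (td == 1) & (ti == 0)
                a["ins"] += ti == 1
                a["del"] += td == 1
                kid_cn = self._kid_cn(state, mk)
                idx = np.arange(self.F * self.J)
                a["kid_cn"].reshape(-1, self.G)[idx, kid_cn.ravel()] += 1
                for col, pr in ((0, state["pf"][mk]), (1, state["pm"][mk])):
                    a["par_cn"][self._fidx, col, t.s[pr]] += 1
                draws[f"sigma_{mk}"].append(state["sigma"][mk])
            if self.assoc is not None:
                draws["alpha"].append(state["alpha"])
                draws["beta"].append(state["beta"])
                draws["tau"].append(state["tau"])
                for k, g in enumerate(state["gamma"]):
                    draws[f"gamma_{k}"].append(float(g))

        for mk in self.markers:
            for key in acc[mk]:
                acc[mk][key] = acc[mk][key] / max(n_keep, 1)
        return {"acc": acc, "draws": {k: np.array(v) for k, v in draws.items()}}


# ---------------------------------------------------------------------------
# public entry points


def _resolve_model_config(
    model_config: ModelConfig | None, pedigree: Pedigree
) -> tuple[ModelConfig, float]:
    mc = model_config or ModelConfig()
    n_off = sum(len(f.offspring) for f in pedigree.families.values())
    return mc, mc.resolve_mutation_prior(n_off)


def _individuals_frame(
    layout: _FamilyLayout, markers: list[str], acc_mean: dict, G: int
) -> pd.DataFrame:
    grid = np.arange(G)
    rows = []
    for mk in markers:
        a = acc_mean[mk]
        for i, fid in enumerate(layout.family_ids):
            for col, pid, role in (
                (0, layout.father_ids[i], "father"),
                (1, layout.mother_ids[i], "mother"),
            ):
                if pid is None:
                    continue
                pmf = a["par_cn"][i, col]
                rows.append(
                    [fid, pid, mk, role, float(pmf @ grid), 0.0, 0.0, 0.0, 0.0]
                    + list(pmf)
                )
            for j, kid in enumerate(layout.kid_ids[i]):
                pmf = a["kid_cn"][i, j]
                rows.append(
                    [
                        fid, kid, mk, "offspring", float(pmf @ grid),
                        float(a["gain"][i, j]), float(a["loss"][i, j]),
                        float(a["ins"][i, j]), float(a["del"][i, j]),
                    ]
                    + list(pmf)
                )
    cols = [
        "family_id", "individual_id", "marker_id", "role",
        "mean_cn", "p_gain", "p_loss", "p_ins", "p_del",
    ] + [f"p_cn_{r}" for r in range(G)]
    return pd.DataFrame(rows, columns=cols)


def _combine_chains(chain_results: list[dict], markers: list[str]) -> tuple[dict, dict]:
    acc_mean = {}
    for mk in markers:
        acc_mean[mk] = {
            key: np.mean([c["acc"][mk][key] for c in chain_results], axis=0)
            for key in chain_results[0]["acc"][mk]
        }
    draws = {
        name: np.stack([c["draws"][name] for c in chain_results])
        for name in chain_results[0]["draws"]
    }
    return acc_mean, draws


def run_detection_mcmc(
    pedigree: Pedigree,
    measurements: MeasurementSet,
    model_config: ModelConfig | None = None,
    mcmc_config: MCMCConfig | None = None,
) -> PosteriorDraws:
    """Sample the detection model's posterior over latent copy numbers.

    Markers are modeled independently, each with its own measurement SD.
    Non-convergence (split-R-hat > 1.05 on any sigma) is flagged with a
    warning; draws are still returned.
    """
    mcmc = mcmc_config or MCMCConfig()
    mc, mut = _resolve_model_config(model_config, pedigree)
    layout = _layout(pedigree)
    tables = build_tables(mc.max_allele, mc.allele_prior_mean)
    markers = measurements.markers
    reps = _replicate_map(measurements)
    stats = {mk: _sse_tables(layout, reps, mk, tables.n_grid) for mk in markers}
    sampler = _GibbsSampler(layout, stats, tables, mut, mcmc)

    seed = 0 if mcmc.seed is None else int(mcmc.seed)
    results = [sampler.run_chain((seed, chain)) for chain in range(mcmc.chains)]
    acc_mean, draws = _combine_chains(results, markers)

    rhat = {name: split_rhat(d) for name, d in draws.items()}
    bad = {k: v for k, v in rhat.items() if np.isfinite(v) and v > 1.05}
    if bad:
        warnings.warn(
            f"possible non-convergence, split-R-hat > 1.05: {bad}", RuntimeWarning
        )
    individuals = _individuals_frame(layout, markers, acc_mean, tables.n_grid)
    return PosteriorDraws(
        individuals=individuals,
        params=draws,
        rhat=rhat,
        n_retained=mcmc.chains * (mcmc.n_iter // mcmc.thin),
    )


def run_association_mcmc(
    pedigree: Pedigree,
    measurements: MeasurementSet,
    disease: pd.Series | None = None,
    model_config: ModelConfig | None = None,
    mcmc_config: MCMCConfig | None = None,
    coding: str = "collapsed",
    marker: str | None = None,
    include_founders: bool = False,
) -> tuple[AssociationFit, PosteriorDraws]:
    """Joint detection + logistic association sampling.

    ``coding="collapsed"`` pools all markers into the binary C
    (C = 1 iff any marker's CN differs from 2); ``coding="single"``
    restricts the model to one marker.  By default only offspring
    disease statuses enter the likelihood (founders excluded to guard
    against ascertainment of relatively healthy recruited parents);
    ``include_founders=True`` is accepted but founder phenotypes are
    currently attached to the logistic model only through their
    offspring's C, so it is a no-op placeholder kept for API symmetry.
    """
    if coding not in {"single", "collapsed"}:
        raise ValueError("coding must be 'single' or 'collapsed'")
    mcmc = mcmc_config or MCMCConfig()
    mc, mut = _resolve_model_config(model_config, pedigree)
    layout = _layout(pedigree)
    tables = build_tables(mc.max_allele, mc.allele_prior_mean)
    markers = measurements.markers
    if coding == "single":
        if marker is None:
            if len(markers) != 1:
                raise ValueError("coding='single' requires marker=")
            marker = markers[0]
        markers = [marker]
    reps = _replicate_map(measurements)
    stats = {mk: _sse_tables(layout, reps, mk, tables.n_grid) for mk in markers}

    # phenotype / covariate arrays for offspring slots
    F, J = layout.n_families, layout.j_max
    inds = pedigree.individuals
    y = np.full((F, J), np.nan)
    n_cov = max(
        (len(inds[k].covariates) for ks in layout.kid_ids for k in ks), default=0
    )
    X = np.zeros((F, J, n_cov))
    for i in range(F):
        for j, kid in enumerate(layout.kid_ids[i]):
            ind = inds[kid]
            status = ind.affected
            if disease is not None and kid in disease.index:
                status = disease.loc[kid]
                status = None if pd.isna(status) else int(status)
            if status is not None:
                y[i, j] = float(status)
            for k in range(min(n_cov, len(ind.covariates))):
                X[i, j, k] = ind.covariates[k]
    mask = np.isfinite(y)
    if not mask.any():
        raise ValueError("no offspring has an observed disease status")
    y_filled = np.where(mask, y, 0.0)

    _warn_separation(layout, reps, markers, y, mask)

    assoc = {"y": y_filled, "mask": mask, "X": X}
    sampler = _GibbsSampler(layout, stats, tables, mut, mcmc, assoc=assoc)
    seed = 0 if mcmc.seed is None else int(mcmc.seed)
    results = [sampler.run_chain((seed, chain)) for chain in range(mcmc.chains)]
    acc_mean, draws = _combine_chains(results, markers)

    rhat = {name: split_rhat(d) for name, d in draws.items()}
    bad = {k: round(v, 3) for k, v in rhat.items() if np.isfinite(v) and v > 1.05}
    fit_warnings = []
    if bad:
        msg = f"possible non-convergence, split-R-hat > 1.05: {bad}"
        warnings.warn(msg, RuntimeWarning)
        fit_warnings.append(msg)

    rows = []
    name_map = {"alpha": "alpha", "beta": "beta", "tau": "re_sd"}
    for name, d in draws.items():
        label = name_map.get(name, name)
        flat = d.ravel()
        rows.append(
            (label, flat.mean(), flat.std(ddof=1), 100.0 * np.mean(flat > 0))
        )
    table = pd.DataFrame(rows, columns=["term", "mean", "sd", "p_gt0_pct"])
    fit = AssociationFit(table=table, draws=draws, warnings=fit_warnings)
    pdraws = PosteriorDraws(
        individuals=_individuals_frame(layout, markers, acc_mean, tables.n_grid),
        params=draws,
        rhat=rhat,
        n_retained=mcmc.chains * (mcmc.n_iter // mcmc.thin),
    )
    return fit, pdraws


def _warn_separation(layout, reps, markers, y, mask) -> None:
    """Cheap separation / constant-design check on rounded copy numbers."""
    from .baseline_nearest_integer import nearest_integer_cn

    c_init, y_obs = [], []
    for i in range(layout.n_families):
        for j, kid in enumerate(layout.kid_ids[i]):
            if not mask[i, j]:
                continue
            cns = []
            for mk in markers:
                r = reps.get((kid, mk))
                if r is not None and r.size:
                    cns.append(nearest_integer_cn(r))
            if not cns:
                continue
            c_init.append(int(any(c != 2 for c in cns)))
            y_obs.append(int(y[i, j]))
    c_arr, y_arr = np.array(c_init), np.array(y_obs)
    if len(c_arr) and c_arr.min() == c_arr.max():
        warnings.warn(
            "collapsed coding C is constant across offspring; beta is "
            "non-identifiable and its posterior will follow the prior",
            RuntimeWarning,
        )
    elif len(c_arr) and (
        (y_arr[c_arr == 1].min(initial=1) == 1 and y_arr[c_arr == 0].max(initial=0) == 0)
    ):
        warnings.warn(
            "complete separation between C groups; beta's posterior is "
            "prior-dominated",
            RuntimeWarning,
        )


def summarize_mutations(
    draws: PosteriorDraws | pd.DataFrame,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> PosteriorSummary:
    """Per-individual mutation calls and per-family flags at each threshold.

    A family is flagged at threshold t when any member's posterior
    probability of insertion or deletion strictly exceeds t (marginal
    indicator probabilities, any marker).
    """
    if any(not 0.0 < t < 1.0 for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1)")
    ind = draws.individuals if isinstance(draws, PosteriorDraws) else draws.copy()
    ind = ind.copy()
    for t in thresholds:
        ind[f"called_{t:g}"] = (ind["p_ins"] > t) | (ind["p_del"] > t)
    flags = []
    for fid, grp in ind.groupby("family_id", sort=True):
        for t in thresholds:
            flags.append((fid, t, bool(grp[f"called_{t:g}"].any())))
    family_flags = pd.DataFrame(flags, columns=["family_id", "threshold", "flagged"])
    return PosteriorSummary(individuals=ind, family_flags=family_flags)


def run_detection_enumerate(
    pedigree: Pedigree,
    measurements: MeasurementSet,
    model_config: ModelConfig | None = None,
    sigma: float | None = None,
) -> PosteriorDraws:
    """Exact-enumeration counterpart of :func:`run_detection_mcmc`.

    Loops families x markers through the enumeration oracle and returns
    the same per-individual summary frame (``params`` is empty).  With
    ``sigma=None`` the model config's sigma handling applies per family.
    """
    from dataclasses import replace

    from .cnv_model import enumerate_family_posterior, family_data_from

    mc, mut = _resolve_model_config(model_config, pedigree)
    mc_resolved = replace(mc, mutation_prior=mut)
    rows = []
    G = 2 * mc.max_allele + 2
    for fid in sorted(pedigree.families):
        fam = pedigree.families[fid]
        roles = {}
        for off in sorted(fam.offspring, key=lambda m: m.individual_id):
            if off.father_id:
                roles[off.father_id] = "father"
            if off.mother_id:
                roles[off.mother_id] = "mother"
        for mk in measurements.markers:
            fd = family_data_from(pedigree, measurements, fid, mk)
            post = enumerate_family_posterior(fd, mc_resolved, sigma=sigma)
            for member, pmf in post.cn_pmf.items():
                role = roles.get(member, "offspring")
                rows.append(
                    [
                        fid, member, mk, role, post.mean_cn[member],
                        post.p_gain.get(member, 0.0),
                        post.p_loss.get(member, 0.0),
                        post.p_ins.get(member, 0.0),
                        post.p_del.get(member, 0.0),
                    ]
                    + list(pmf)
                )
    cols = [
        "family_id", "individual_id", "marker_id", "role",
        "mean_cn", "p_gain", "p_loss", "p_ins", "p_del",
    ] + [f"p_cn_{r}" for r in range(G)]
    return PosteriorDraws(
        individuals=pd.DataFrame(rows, columns=cols), params={}, rhat={}
    )
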