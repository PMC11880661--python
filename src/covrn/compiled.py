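"""Fit-ready joint model: log posterior density and analytic gradient.

A compiled model holds the data arrays, index maps and parameter layout
for one bivariate model variant and evaluates ``logp_grad`` on an
unconstrained parameter vector. Latent effect pairs are parameterized
non-centered: raw standard-normal vectors are scaled by the latent SDs
and rotated by the context-specific correlation ``tanh(X3 @ beta_r)``.
Gaussian traits measured once per (subject, context) contribute their
latent component deterministically (the residual *is* the latent), so
only the non-Gaussian side of a pair carries sampled latents.

Gradients are hand-derived and checked against finite differences in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

_LOG2PI = np.log(2.0 * np.pi)


def _floor_at(x, lo=1e-12):
    return np.maximum(x, lo)


@dataclass
class _TraitBlock:
    """Per-trait data arrays in model (standardized) coordinates."""

    y: np.ndarray  # (n,) float (ordinal stored as int-valued float)
    X: np.ndarray  # (n, p) design incl. intercept unless ordinal
    ctx: np.ndarray  # (n,) int context index
    unit: np.ndarray  # (n,) int latent-unit index
    family: str  # gaussian | poisson_log | ordinal_logit
    role: str  # residual | direct | repeated | paired
    zero_truncated: bool = False
    n_categories: int = 0
    col_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.loggamma_const = (
            float(gammaln(self.y + 1.0).sum()) if self.family == "poisson_log" else 0.0
        )


class CompiledModel:
    """Joint bivariate model over an unconstrained parameter vector.

    Construction is handled by :func:`covrn.modelspec.build_model`; this
    class only knows about arrays and the parameter layout.
    """

    def __init__(
        self,
        variant: str,
        t1: _TraitBlock,
        t2: _TraitBlock,
        X3: np.ndarray,
        x3_names: list[str],
        unit_ctx: np.ndarray,
        n_contexts: int,
        include_year: tuple[bool, bool],
        priors,
        standardization: dict,
        trait_names: tuple[str, str] = ("trait1", "trait2"),
    ):
        self.variant = variant
        self.t1, self.t2 = t1, t2
        self.X3 = np.asarray(X3, dtype=float)
        self.x3_names = list(x3_names)
        self.unit_ctx = np.asarray(unit_ctx, dtype=np.intp)
        self.n_units = int(unit_ctx.shape[0])
        self.n_contexts = int(n_contexts)
        self.include_year = tuple(include_year)
        self.priors = priors
        self.standardization = standardization
        self.trait_names = trait_names

        # which side of the latent pair is sampled vs deterministic
        self.side_stoch = (t1.role in ("direct", "repeated", "paired"),
                          t2.role in ("direct", "repeated", "paired"))

        # quantity-quality coupling: trait 1's measurement count per unit
        # equals trait 2's count value (offspring masses vs litter size).
        # Replicates must then regenerate trait 1's rows from the replicated
        # litter sizes, or the mass-fecundity correlation is lost.
        self.hybrid_coupled = False
        if variant == "hybrid" and t2.family in ("poisson_log", "ordinal_logit"):
            counts1 = np.bincount(t1.unit, minlength=self.n_units)
            counts_obs = np.zeros(self.n_units)
            counts_obs[t2.unit] = t2.y
            if counts1.size and counts1.min() >= 1 and np.array_equal(counts1, counts_obs):
                first = np.full(self.n_units, len(t1.y), dtype=np.intp)
                np.minimum.at(first, t1.unit, np.arange(len(t1.y), dtype=np.intp))
                # coupling additionally requires unit-level trait-1 covariates
                if np.array_equal(t1.X, t1.X[first[t1.unit]]):
                    self.hybrid_coupled = True
                    self._t1_first_row = first

        self._build_layout()

    # ------------------------------------------------------------------ layout
    def _build_layout(self) -> None:
        self.sl: dict[str, slice] = {}
        pos = 0

        def add(name, k):
            nonlocal pos
            if k > 0:
                self.sl[name] = slice(pos, pos + k)
                pos += k

        add("b1", self.t1.X.shape[1])
        add("b2", self.t2.X.shape[1])
        add("br", self.X3.shape[1])
        if self.variant == "full":
            add("bre", self.X3.shape[1])

        sd_names = []
        if self.variant == "non_repeated":
            sd_names += ["sd_o1", "sd_o2"]
        elif self.variant == "hybrid":
            sd_names += ["sd_alpha1", "sd_eps1", "sd_o2"]
        else:  # full
            sd_names += ["sd_alpha1", "sd_alpha2", "sd_eps1", "sd_eps2"]
        if self.include_year[0]:
            sd_names.append("sd_year1")
        if self.include_year[1]:
            sd_names.append("sd_year2")
        self.sd_names = sd_names
        add("log_sd", len(sd_names))
        self._sd_pos = {n: i for i, n in enumerate(sd_names)}

        for tag, t in (("thr1", self.t1), ("thr2", self.t2)):
            if t.family == "ordinal_logit":
                add(tag, t.n_categories - 1)
        if self.include_year[0]:
            add("v1", self.n_contexts)
        if self.include_year[1]:
            add("v2", self.n_contexts)
        if self.side_stoch[0]:
            add("u1", self.n_units)
        if self.side_stoch[1]:
            add("u2", self.n_units)
        self.n_params = pos

        # reported (top-level) parameter names
        names = []
        names += [f"b1_{c}" for c in self.t1.col_names]
        names += [f"b2_{c}" for c in self.t2.col_names]
        names += [f"br_{c}" for c in self.x3_names]
        if self.variant == "full":
            names += [f"bre_{c}" for c in self.x3_names]
        names += sd_names
        for tag, t in (("thr1", self.t1), ("thr2", self.t2)):
            if t.family == "ordinal_logit":
                names += [f"theta{k + 1}" for k in range(t.n_categories - 1)]
        self.report_names = names

    # ---------------------------------------------------------------- helpers
    def _sd_slice_index(self, name: str) -> int:
        return self.sl["log_sd"].start + self._sd_pos[name]

    def report_draws(self, thetas: np.ndarray) -> dict[str, np.ndarray]:
        """Map raw parameter rows to named, constrained reported values."""
        thetas = np.atleast_2d(thetas)
        out: dict[str, np.ndarray] = {}
        i = 0
        for blk in ("b1", "b2", "br", "bre"):
            if blk not in self.sl:
                continue
            for j in range(self.sl[blk].start, self.sl[blk].stop):
                out[self.report_names[i]] = thetas[:, j]
                i += 1
        for k, name in enumerate(self.sd_names):
            out[name] = np.exp(thetas[:, self.sl["log_sd"].start + k])
            i += 1
        for tag in ("thr1", "thr2"):
            if tag in self.sl:
                raw = thetas[:, self.sl[tag]]
                theta = np.empty_like(raw)
                theta[:, 0] = raw[:, 0]
                for k in range(1, raw.shape[1]):
                    theta[:, k] = theta[:, k - 1] + np.exp(raw[:, k])
                for k in range(raw.shape[1]):
                    out[self.report_names[i]] = theta[:, k]
                    i += 1
        return out

    def _thresholds(self, theta, tag):
        raw = theta[self.sl[tag]]
        th = np.empty_like(raw)
        th[0] = raw[0]
        for k in range(1, raw.shape[0]):
            th[k] = th[k - 1] + np.exp(raw[k])
        return raw, th

    # --------------------------------------------------------------- densities
    def logp_grad(self, theta: np.ndarray, prior_only: bool = False):
        """Return (log posterior, gradient) at unconstrained ``theta``."""
        pr = self.priors
        g = np.zeros_like(theta)
        lp = 0.0

        # --- coefficient priors
        for blk in ("b1", "b2", "br", "bre"):
            if blk not in self.sl:
                continue
            x = theta[self.sl[blk]]
            z = (x - pr.coef_loc) / pr.coef_scale
            lp += float(np.sum(-0.5 * z * z) - x.size * np.log(pr.coef_scale)) - 0.5 * _LOG2PI * x.size
            g[self.sl[blk]] += -z / pr.coef_scale

        # --- SD priors: sigma ~ Exponential(rate), sampled as log sigma
        if "log_sd" in self.sl:
            ls = theta[self.sl["log_sd"]]
            sd = np.exp(np.minimum(ls, 40.0))
            lp += float(np.sum(np.log(pr.sd_rate) - pr.sd_rate * sd + ls))
            g[self.sl["log_sd"]] += 1.0 - pr.sd_rate * sd
        else:
            sd = np.empty(0)

        # --- ordered threshold priors (Normal on theta scale + log-Jacobian)
        thr = {}
        for tag in ("thr1", "thr2"):
            if tag not in self.sl:
                continue
            raw, th = self._thresholds(theta, tag)
            thr[tag] = th
            z = (th - pr.threshold_loc) / pr.threshold_scale
            lp += float(np.sum(-0.5 * z * z) - th.size * np.log(pr.threshold_scale)) - 0.5 * _LOG2PI * th.size
            lp += float(np.sum(raw[1:]))  # Jacobian of the ordered transform
            gth = -z / pr.threshold_scale
            # theta_k depends on raw_j for j <= k: d theta_k / d raw_0 = 1,
            # d theta_k / d raw_j = exp(raw_j) for 1 <= j <= k
            graw = np.empty_like(raw)
            csum = np.cumsum(gth[::-1])[::-1]  # sum_{k >= j} gth_k
            graw[0] = csum[0]
            if raw.shape[0] > 1:
                graw[1:] = csum[1:] * np.exp(raw[1:]) + 1.0
            g[self.sl[tag]] += graw

        # --- standard-normal priors on raw latents
        for blk in ("v1", "v2", "u1", "u2"):
            if blk not in self.sl:
                continue
            x = theta[self.sl[blk]]
            lp += float(np.sum(-0.5 * x * x)) - 0.5 * _LOG2PI * x.size
            g[self.sl[blk]] += -x

        if prior_only:
            return lp, g

        ls_idx = lambda name: self._sd_pos[name]
        sd_of = lambda name: sd[self._sd_pos[name]]

        # --- linear predictors (without latent pair contribution)
        b1 = theta[self.sl["b1"]] if "b1" in self.sl else np.empty(0)
        b2 = theta[self.sl["b2"]] if "b2" in self.sl else np.empty(0)
        eta1 = self.t1.X @ b1 if b1.size else np.zeros(self.t1.y.shape[0])
        eta2 = self.t2.X @ b2 if b2.size else np.zeros(self.t2.y.shape[0])
        delta = [None, None]
        for j, (tag_v, tag_sd, t, eta) in enumerate(
            (("v1", "sd_year1", self.t1, eta1), ("v2", "sd_year2", self.t2, eta2))
        ):
            if self.include_year[j]:
                d = sd_of(tag_sd) * theta[self.sl[tag_v]]
                delta[j] = d
                eta = eta + d[t.ctx]
                if j == 0:
                    eta1 = eta
                else:
                    eta2 = eta

        # --- correlation reaction norm
        br = theta[self.sl["br"]]
        eta_r = self.X3 @ br
        r_c = np.tanh(eta_r)
        r = r_c[self.unit_ctx]
        s = np.sqrt(_floor_at(1.0 - r * r))

        U = self.n_units
        side = self.side_stoch
        sd1_name = "sd_o1" if self.variant == "non_repeated" else "sd_alpha1"
        sd2_name = "sd_alpha2" if self.variant == "full" else "sd_o2"
        sd1, sd2 = sd_of(sd1_name), sd_of(sd2_name)

        # --- latent pair construction
        o_det = [None, None]  # deterministic latents (from Gaussian residuals)
        if not side[0]:
            res1 = self.t1.y - eta1
            o1 = np.zeros(U)
            o1[self.t1.unit] = res1
        if not side[1]:
            res2 = self.t2.y - eta2
            o2 = np.zeros(U)
            o2[self.t2.unit] = res2
        if side[0] and side[1]:
            u1v = theta[self.sl["u1"]]
            u2v = theta[self.sl["u2"]]
            o1 = sd1 * u1v
            o2 = sd2 * (r * u1v + s * u2v)
        elif not side[0] and side[1]:
            u2v = theta[self.sl["u2"]]
            q1 = o1 / sd1
            o2 = sd2 * (r * q1 + s * u2v)
        elif side[0] and not side[1]:
            u1v = theta[self.sl["u1"]]
            q2 = o2 / sd2
            o1 = sd1 * (r * q2 + s * u1v)
        # both deterministic: handled in pair-density section below

        # --- likelihood terms; produce g_pair (dL/do per unit) and g_eta per obs
        g_eta1 = np.zeros_like(eta1)
        g_eta2 = np.zeros_like(eta2)
        g_pair = [np.zeros(U), np.zeros(U)]

        for j, t in ((0, self.t1), (1, self.t2)):
            eta = eta1 if j == 0 else eta2
            o = o1 if j == 0 else o2
            if t.role == "direct":
                mu = eta + o[t.unit]
                ll, gmu, extra = self._family_loglik(t, mu, theta, g)
                lp += ll
                if j == 0:
                    g_eta1 += gmu
                else:
                    g_eta2 += gmu
                g_pair[j] += np.bincount(t.unit, weights=gmu, minlength=U)
            elif t.role == "repeated":
                sde = sd_of("sd_eps1")
                resid = t.y - eta - o[t.unit]
                z = resid / sde
                lp += float(np.sum(-0.5 * z * z) - t.y.size * np.log(sde)) - 0.5 * _LOG2PI * t.y.size
                gmu = z / sde
                g[self._sd_slice_index("sd_eps1")] += float(np.sum(z * z) - t.y.size)
                if j == 0:
                    g_eta1 += gmu
                else:
                    g_eta2 += gmu
                g_pair[j] += np.bincount(t.unit, weights=gmu, minlength=U)
            # residual role: handled through pair density below
            # paired role (full variant): handled after pair density

        # --- full-variant paired residual density (within-individual pair)
        if self.variant == "full":
            bre = theta[self.sl["bre"]]
            re_c = np.tanh(self.X3 @ bre)
            re = re_c[self.t1.ctx]
            se1, se2 = sd_of("sd_eps1"), sd_of("sd_eps2")
            e1 = self.t1.y - eta1 - o1[self.t1.unit]
            e2 = self.t2.y - eta2 - o2[self.t2.unit]
            p1, p2 = e1 / se1, e2 / se2
            om = _floor_at(1.0 - re * re)
            Q = p1 * p1 - 2.0 * re * p1 * p2 + p2 * p2
            lp += float(
                np.sum(-_LOG2PI - np.log(se1) - np.log(se2) - 0.5 * np.log(om) - Q / (2.0 * om))
            )
            gq1 = -(p1 - re * p2) / om
            gq2 = -(p2 - re * p1) / om
            ge1, ge2 = gq1 / se1, gq2 / se2
            g_eta1 -= ge1
            g_eta2 -= ge2
            g_pair[0] -= np.bincount(self.t1.unit, weights=ge1, minlength=U)
            g_pair[1] -= np.bincount(self.t2.unit, weights=ge2, minlength=U)
            g[self._sd_slice_index("sd_eps1")] += float(np.sum(-1.0 + p1 * (p1 - re * p2) / om))
            g[self._sd_slice_index("sd_eps2")] += float(np.sum(-1.0 + p2 * (p2 - re * p1) / om))
            dldre = re / om + p1 * p2 / om - Q * re / (om * om)
            dldre_c = np.bincount(self.t1.ctx, weights=dldre, minlength=self.n_contexts)
            g[self.sl["bre"]] += self.X3.T @ (dldre_c * (1.0 - re_c * re_c))

        # --- latent pair density and backprop through the construction
        ls_sl = self.sl["log_sd"].start
        g1p, g2p = g_pair
        if side[0] and side[1]:
            g[self.sl["u1"]] += g1p * sd1 + g2p * sd2 * r
            g[self.sl["u2"]] += g2p * sd2 * s
            g[ls_sl + ls_idx(sd1_name)] += float(np.dot(g1p, o1))
            g[ls_sl + ls_idx(sd2_name)] += float(np.dot(g2p, o2))
            dldr = g2p * sd2 * (u1v - (r / s) * u2v)
        elif not side[0] and side[1]:
            lp += float(np.sum(-0.5 * q1 * q1) - U * np.log(sd1)) - 0.5 * _LOG2PI * U
            g[self.sl["u2"]] += g2p * sd2 * s
            g[ls_sl + ls_idx(sd2_name)] += float(np.dot(g2p, o2))
            g[ls_sl + ls_idx(sd1_name)] += float(np.sum(q1 * q1) - U) + float(
                np.dot(g2p, -sd2 * r * q1)
            )
            dldr = g2p * sd2 * (q1 - (r / s) * u2v)
            h1 = -q1 / sd1 + g2p * sd2 * r / sd1
            g_eta1 -= h1[self.t1.unit]
        elif side[0] and not side[1]:
            lp += float(np.sum(-0.5 * q2 * q2) - U * np.log(sd2)) - 0.5 * _LOG2PI * U
            g[self.sl["u1"]] += g1p * sd1 * s
            g[ls_sl + ls_idx(sd1_name)] += float(np.dot(g1p, o1))
            g[ls_sl + ls_idx(sd2_name)] += float(np.sum(q2 * q2) - U) + float(
                np.dot(g1p, -sd1 * r * q2)
            )
            dldr = g1p * sd1 * (q2 - (r / s) * u1v)
            h2 = -q2 / sd2 + g1p * sd1 * r / sd2
            g_eta2 -= h2[self.t2.unit]
        else:
            # both Gaussian single-measure: bivariate normal of the residual pair
            q1, q2 = o1 / sd1, o2 / sd2
            om = _floor_at(1.0 - r * r)
            Q = q1 * q1 - 2.0 * r * q1 * q2 + q2 * q2
            lp += float(
                np.sum(-_LOG2PI - np.log(sd1) - np.log(sd2) - 0.5 * np.log(om) - Q / (2.0 * om))
            )
            gq1 = -(q1 - r * q2) / om
            gq2 = -(q2 - r * q1) / om
            g[ls_sl + ls_idx(sd1_name)] += float(np.sum(-1.0 + q1 * (q1 - r * q2) / om))
            g[ls_sl + ls_idx(sd2_name)] += float(np.sum(-1.0 + q2 * (q2 - r * q1) / om))
            dldr = r / om + q1 * q2 / om - Q * r / (om * om)
            h1 = gq1 / sd1
            h2 = gq2 / sd2
            g_eta1 -= h1[self.t1.unit]
            g_eta2 -= h2[self.t2.unit]

        dldr_c = np.bincount(self.unit_ctx, weights=dldr, minlength=self.n_contexts)
        g[self.sl["br"]] += self.X3.T @ (dldr_c * (1.0 - r_c * r_c))

        # --- backprop linear predictors into coefficients and year effects
        for j, (t, g_eta) in enumerate(((self.t1, g_eta1), (self.t2, g_eta2))):
            blk = "b1" if j == 0 else "b2"
            if blk in self.sl and t.X.shape[1]:
                g[self.sl[blk]] += t.X.T @ g_eta
            if self.include_year[j]:
                tag_v = "v1" if j == 0 else "v2"
                tag_sd = "sd_year1" if j == 0 else "sd_year2"
                gd = np.bincount(t.ctx, weights=g_eta, minlength=self.n_contexts)
                g[self.sl[tag_v]] += sd_of(tag_sd) * gd
                g[ls_sl + ls_idx(tag_sd)] += float(np.dot(gd, delta[j]))

        return lp, g

    def _family_loglik(self, t: _TraitBlock, mu, theta, g):
        """Log likelihood and d/d(linear predictor) for direct-role traits.

        Ordinal threshold gradients are accumulated into ``g`` in place.
        """
        y = t.y
        if t.family == "poisson_log":
            lam = np.exp(np.minimum(mu, 40.0))  # clip: overflow region is rejected anyway
            ll = float(np.dot(y, mu) - lam.sum()) - t.loggamma_const
            gmu = y - lam
            if t.zero_truncated:
                # conditioning on y >= 1
                em = np.exp(-lam)
                ll += float(-np.log1p(-np.minimum(em, 1.0 - 1e-12)).sum())
                gmu = gmu - lam * em / _floor_at(1.0 - em)
            return ll, gmu, None
        if t.family == "ordinal_logit":
            tag = "thr1" if t is self.t1 else "thr2"
            th = self._thresholds(theta, tag)[1]
            K = t.n_categories
            yi = y.astype(np.intp)
            lo = np.where(yi == 0, -np.inf, th[np.maximum(yi - 1, 0)] - mu)
            hi = np.where(yi == K - 1, np.inf, th[np.minimum(yi, K - 2)] - mu)
            Flo = np.where(np.isneginf(lo), 0.0, 1.0 / (1.0 + np.exp(-lo)))
            Fhi = np.where(np.isposinf(hi), 1.0, 1.0 / (1.0 + np.exp(-hi)))
            P = _floor_at(Fhi - Flo, 1e-300)
            flo = np.where(np.isfinite(lo), Flo * (1.0 - Flo), 0.0)
            fhi = np.where(np.isfinite(hi), Fhi * (1.0 - Fhi), 0.0)
            gmu = (flo - fhi) / P
            # d logp / d theta_k: +fhi/P where hi uses theta_k (y == k),
            # -flo/P where lo uses theta_k (y == k + 1)
            gth = np.zeros(K - 1)
            contrib_hi = np.where(np.isfinite(hi), fhi / P, 0.0)
            contrib_lo = np.where(np.isfinite(lo), -flo / P, 0.0)
            np.add.at(gth, np.minimum(yi, K - 2), np.where(yi <= K - 2, contrib_hi, 0.0))
            np.add.at(gth, np.maximum(yi - 1, 0), np.where(yi >= 1, contrib_lo, 0.0))
            # chain through the ordered transform
            raw = theta[self.sl[tag]]
            csum = np.cumsum(gth[::-1])[::-1]
            graw = np.empty_like(raw)
            graw[0] = csum[0]
            if raw.shape[0] > 1:
                graw[1:] = csum[1:] * np.exp(raw[1:])
            g[self.sl[tag]] += graw
            return float(np.sum(np.log(P))), gmu, None
        raise ValueError(f"family {t.family!r} cannot take a direct latent role")

    # ----------------------------------------------------------------- initial
    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        """Weakly dispersed start: small coefficients, correlations at 0."""
        theta = np.zeros(self.n_params)
        for blk in ("b1", "b2"):
            if blk in self.sl:
                theta[self.sl[blk]] = 0.1 * rng.standard_normal(
                    self.sl[blk].stop - self.sl[blk].start
                )
        if "log_sd" in self.sl:
            k = self.sl["log_sd"].stop - self.sl["log_sd"].start
            theta[self.sl["log_sd"]] = np.log(0.5) + 0.1 * rng.standard_normal(k)
        for tag in ("thr1", "thr2"):
            if tag in self.sl:
                k = self.sl[tag].stop - self.sl[tag].start
                raw = np.zeros(k)
                raw[0] = -1.0
                raw[1:] = np.log(2.0)
                theta[self.sl[tag]] = raw + 0.05 * rng.standard_normal(k)
        for blk in ("v1", "v2", "u1", "u2"):
            if blk in self.sl:
                k = self.sl[blk].stop - self.sl[blk].start
                theta[self.sl[blk]] = 0.1 * rng.standard_normal(k)
        return theta

    # --------------------------------------------------------------- replicate
    def simulate_replicate(self, rng: np.random.Generator, theta: np.ndarray):
        """Draw one replicated dataset (y1_rep, y2_rep) under the model at
        ``theta``, redrawing all latent effects from their priors."""
        rep = self.report_draws(theta[None, :])
        get = lambda n: float(rep[n][0])
        b1 = theta[self.sl["b1"]] if "b1" in self.sl else np.empty(0)
        b2 = theta[self.sl["b2"]] if "b2" in self.sl else np.empty(0)
        eta1 = self.t1.X @ b1 if b1.size else np.zeros(self.t1.y.shape[0])
        eta2 = self.t2.X @ b2 if b2.size else np.zeros(self.t2.y.shape[0])
        if self.include_year[0]:
            d1 = get("sd_year1") * rng.standard_normal(self.n_contexts)
            eta1 = eta1 + d1[self.t1.ctx]
        if self.include_year[1]:
            d2 = get("sd_year2") * rng.standard_normal(self.n_contexts)
            eta2 = eta2 + d2[self.t2.ctx]
        br = theta[self.sl["br"]]
        r = np.tanh(self.X3 @ br)[self.unit_ctx]
        s = np.sqrt(_floor_at(1.0 - r * r))
        sd1 = get("sd_o1" if self.variant == "non_repeated" else "sd_alpha1")
        sd2 = get("sd_alpha2" if self.variant == "full" else "sd_o2")
        w1 = rng.standard_normal(self.n_units)
        w2 = rng.standard_normal(self.n_units)
        o1 = sd1 * w1
        o2 = sd2 * (r * w1 + s * w2)

        def draw(t: _TraitBlock, eta, o, sd_within, tag):
            mu = eta + o[t.unit]
            if t.role == "repeated" or t.role == "paired":
                return mu + sd_within * rng.standard_normal(mu.shape[0])
            if t.family == "gaussian":  # residual role: o is the residual
                return mu
            if t.family == "poisson_log":
                lam = np.exp(np.minimum(mu, 30.0))
                if t.zero_truncated:
                    from .simulate import _zero_truncated_poisson

                    return _zero_truncated_poisson(rng, lam).astype(float)
                return rng.poisson(lam).astype(float)
            if t.family == "ordinal_logit":
                th = self._thresholds(theta, tag)[1]
                cum = 1.0 / (1.0 + np.exp(-(th[None, :] - mu[:, None])))
                u = rng.random(mu.shape[0])
                return (u[:, None] >= cum).sum(axis=1).astype(float)
            raise ValueError(t.family)

        sde1 = get("sd_eps1") if "sd_eps1" in self.sd_names else 0.0
        sde2 = get("sd_eps2") if "sd_eps2" in self.sd_names else 0.0
        if self.hybrid_coupled:
            # generative order matters: replicated litter sizes determine how
            # many offspring-mass rows each mother-year contributes
            y2 = draw(self.t2, eta2, o2, sde2, "thr2")
            counts = np.zeros(self.n_units, dtype=np.intp)
            counts[self.t2.unit] = y2.astype(np.intp)
            eta1_u = eta1[self._t1_first_row]  # trait-1 covariates are unit-level
            mu1 = np.repeat(eta1_u + o1, counts)
            y1 = mu1 + sde1 * rng.standard_normal(mu1.shape[0])
            return y1, y2
        if self.variant == "full":
            re = np.tanh(self.X3 @ theta[self.sl["bre"]])[self.t1.ctx]
            se = np.sqrt(_floor_at(1.0 - re * re))
            z1 = rng.standard_normal(self.t1.y.shape[0])
            z2 = rng.standard_normal(self.t2.y.shape[0])
            e1 = sde1 * z1
            e2 = sde2 * (re * z1 + se * z2)
            y1 = eta1 + o1[self.t1.unit] + e1
            y2 = eta2 + o2[self.t2.unit] + e2
            return y1, y2
        y1 = draw(self.t1, eta1, o1, sde1, "thr1")
        y2 = draw(self.t2, eta2, o2, sde2, "thr2")
        return y1, y2
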