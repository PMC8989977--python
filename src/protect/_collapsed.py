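"""Collapsed log-posterior of the structural causal model.

The per-patient latents (U_f, U_b) are integrated out of the joint density
with probabilists' Gauss-Hermite quadrature, leaving a smooth posterior over
the ~35 structural parameters that gradient-based MCMC mixes through
rapidly.  The survival term factorizes over the two latent axes
(exp(eta_f + eta_b) = exp(eta_f) * exp(eta_b)), so transcendental work is
O(n * (Q_f + Q_b)) with only cheap products on the Q_f x Q_b grid.

Everything is analytically differentiated; gradients of the marginal
log-likelihood are posterior-weighted expectations of the per-node score
functions (Fisher's identity), with the quadrature responsibilities playing
the role of the latent posterior.

An optional extra standard-normal confounder U2 with *fixed* coefficients
(theta_treatment on the treatment logit, theta_outcome on the log-hazard)
is folded into the fitness quadrature axis; it is the machinery behind the
omitted-confounder sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from ._design import CohortData, ModelDesign
from ._numutil import gauss_hermite, sigmoid, softplus
from .dag import HISTOLOGY_LEVELS


class CollapsedModel:
    def __init__(
        self,
        design: ModelDesign,
        data: CohortData,
        priors=None,
        quad_fitness: int = 7,
        quad_behavior: int = 7,
        quad_extra: int = 5,
        use_kernel: bool | None = None,
    ):
        from ._kernel import HAVE_NUMBA
        from .params import PriorSpec

        self.design = design
        self.data = data
        self.priors = priors or PriorSpec()

        layout = design.param_layout
        self.names = [name for name, _ in layout]
        self.positive = np.array([pos for _, pos in layout])
        self.idx = {name: i for i, name in enumerate(self.names)}
        self.n_params = len(self.names)

        # quadrature grids; the fitness axis absorbs the fixed extra confounder
        zf, wf = gauss_hermite(quad_fitness) if design.has_fitness else (np.zeros(1), np.ones(1))
        if design.extra_confounder is not None:
            z2, w2 = gauss_hermite(quad_extra)
            self.zf = np.repeat(zf, len(z2))
            self.u2 = np.tile(z2, len(zf))
            self.wf = np.repeat(wf, len(z2)) * np.tile(w2, len(zf))
        else:
            self.zf, self.wf = zf, wf
            self.u2 = np.zeros_like(zf)
        self.zb, self.wb = (
            gauss_hermite(quad_behavior) if design.has_behavior else (np.zeros(1), np.ones(1))
        )

        # prior scales per parameter
        scale = np.full(self.n_params, self.priors.scale_coef)
        scale[self.positive] = self.priors.scale_loading
        scale[self.idx["weibull_shape"]] = self.priors.scale_shape
        self.prior_scale = scale

        # hot-loop precomputations
        self._i_tcovs = np.array(
            [self.idx[f"treatment_{c}"] for c in design.treatment_covs], dtype=int
        )
        self._i_ocovs = np.array(
            [self.idx[f"outcome_{c}"] for c in design.outcome_covs], dtype=int
        )
        self._i_icovs = np.array(
            [self.idx[f"interaction_{c}"] for c in design.interaction_covs], dtype=int
        )
        self._onehot = (
            np.eye(len(HISTOLOGY_LEVELS))[data.y_cat] if data.y_cat is not None else None
        )

        # node groupings and packed target arrays for the compiled kernel
        self.use_kernel = HAVE_NUMBA if use_kernel is None else use_kernel
        self._fit_nodes = [b for b in design.binary_nodes if b.latent == "fitness"]
        self._beh_nodes = [b for b in design.binary_nodes if b.latent == "behavior"]
        self._orphan_nodes = [b for b in design.binary_nodes if b.latent is None]
        self._YF = (
            np.array([data.y_binary[b.name] for b in self._fit_nodes])
            if self._fit_nodes
            else np.zeros((0, data.n))
        )
        self._YB = (
            np.array([data.y_binary[b.name] for b in self._beh_nodes])
            if self._beh_nodes
            else np.zeros((0, data.n))
        )
        self._signs_f = np.array([float(b.sign) for b in self._fit_nodes])
        self._signs_b = np.array([float(b.sign) for b in self._beh_nodes])
        self._age = data.age if data.age is not None else np.zeros(data.n)
        ia = lambda fmt, nodes: np.array(
            [self.idx[fmt.format(b.name)] for b in nodes], dtype=int
        )
        self._i_af = ia("{}_intercept", self._fit_nodes)
        self._i_bf = ia("{}_loading", self._fit_nodes)
        self._i_ab = ia("{}_intercept", self._beh_nodes)
        self._i_bb = ia("{}_loading", self._beh_nodes)
        n_fp, n_bp = len(self._fit_nodes), len(self._beh_nodes)
        self._buf = tuple(
            np.zeros(s)
            for s in (max(n_fp, 1), max(n_fp, 1), max(n_bp, 1), max(n_bp, 1), 4,
                      data.n, data.n, data.n, 7)
        )
        if data.y_cat is not None:
            self._cat1 = np.ascontiguousarray(self._onehot[:, 1])
            self._cat2 = np.ascontiguousarray(self._onehot[:, 2])
        else:
            self._cat1 = self._cat2 = np.zeros(data.n)

    # ------------------------------------------------------------------
    def to_natural(self, x: np.ndarray) -> np.ndarray:
        theta = np.array(x, float)
        theta[self.positive] = np.exp(theta[self.positive])
        return theta

    def to_unconstrained(self, theta: np.ndarray) -> np.ndarray:
        x = np.array(theta, float)
        x[self.positive] = np.log(x[self.positive])
        return x

    def initial_vector(self, rng: np.random.Generator, jitter: float = 0.1) -> np.ndarray:
        return jitter * rng.standard_normal(self.n_params)

    # ------------------------------------------------------------------
    def loglik_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Marginal log-likelihood (latents integrated out) and its gradient
        with respect to the natural-scale parameters."""
        if self.use_kernel:
            return self._loglik_and_grad_kernel(theta)
        return self.loglik_and_grad_numpy(theta)

    def _loglik_and_grad_kernel(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        from ._kernel import collapsed_loglik_grad

        d, data, idx = self.design, self.data, self.idx
        n = data.n
        grad = np.zeros(self.n_params)
        g = lambda name: theta[idx[name]]

        # constant-side (latent-free) nodes handled here, not in the kernel
        ll_const = 0.0
        for bn in self._orphan_nodes:
            y = data.y_binary[bn.name]
            a = g(f"{bn.name}_intercept")
            ll_const += float(np.sum(y * a - softplus(a)))
            grad[idx[f"{bn.name}_intercept"]] += float((y - sigmoid(a)).sum())
        if d.categorical is not None and not d.categorical_latent:
            levels = HISTOLOGY_LEVELS[1:]
            full = np.concatenate(
                [[0.0], [g(f"histology_{lv}_intercept") for lv in levels]]
            )
            logz = np.logaddexp.reduce(full)
            probs = np.exp(full - logz)
            ll_const += float((self._onehot @ (full - logz)).sum())
            for j, lv in enumerate(levels, start=1):
                grad[idx[f"histology_{lv}_intercept"]] += float(
                    (self._onehot[:, j] - probs[j]).sum()
                )
        base_a = (
            g("treatment_intercept") + data.Xt @ theta[self._i_tcovs]
            if d.treatment_covs
            else np.full(n, g("treatment_intercept"))
        )
        treat_in_kernel = d.treat_on_fitness or d.extra_confounder is not None
        if not treat_in_kernel:
            ll_const += float(np.sum(data.A * base_a - softplus(base_a)))
            s0 = data.A - sigmoid(base_a)
            grad[idx["treatment_intercept"]] += s0.sum()
            for j, c in enumerate(d.treatment_covs):
                grad[idx[f"treatment_{c}"]] += float(data.Xt[:, j] @ s0)

        beta_o = theta[self._i_ocovs]
        gamma = theta[self._i_icovs]
        e0 = (
            g("outcome_intercept")
            + g("outcome_treatment") * data.A
            + (data.Xo @ beta_o if d.outcome_covs else 0.0)
            + data.A * (data.Xi @ gamma if d.interaction_covs else 0.0)
        )
        cf = np.zeros(n)
        if d.out_on_fitness:
            cf += g("outcome_fitness")
        if d.interaction_fitness:
            cf += g("interaction_fitness") * data.A

        af, bf = theta[self._i_af], theta[self._i_bf]
        ab, bb = theta[self._i_ab], theta[self._i_bb]
        has_cat = 1 if (d.categorical is not None and d.categorical_latent) else 0
        if has_cat:
            a1 = g("histology_squamous_intercept")
            b1 = g("histology_squamous_loading")
            a2 = g("histology_other_intercept")
            b2 = g("histology_other_loading")
        else:
            a1 = b1 = a2 = b2 = 0.0
        cat1, cat2 = self._cat1, self._cat2
        th_t, th_o = d.extra_confounder if d.extra_confounder is not None else (0.0, 0.0)

        (g_af, g_bf, g_ab, g_bb, g_cat, g_base_a, g_e0, g_cf, g_scalars) = self._buf
        for b in self._buf:
            b.fill(0.0)

        ll = collapsed_loglik_grad(
            self.zf, self.wf, self.u2, th_o,
            self.zb, self.wb,
            self._age, 1 if (d.has_fitness and d.fitness_cause) else 0, g("alpha") if "alpha" in idx else 0.0,
            self._YF, self._signs_f, af, bf,
            self._YB, self._signs_b, ab, bb,
            has_cat, cat1, cat2, a1, b1, a2, b2,
            1 if treat_in_kernel else 0, data.A, base_a,
            g("treatment_fitness") if d.treat_on_fitness else 0.0, th_t,
            1 if d.treat_on_fitness else 0,
            e0, cf, 1 if d.out_on_behavior else 0,
            g("outcome_behavior") if d.out_on_behavior else 0.0,
            g("weibull_shape"), data.log_time, data.event,
            g_af, g_bf, g_ab, g_bb, g_cat, g_base_a, g_e0, g_cf, g_scalars,
        )
        if not np.isfinite(ll):
            return -np.inf, grad

        for j, b in enumerate(self._fit_nodes):
            grad[idx[f"{b.name}_intercept"]] += g_af[j]
            grad[idx[f"{b.name}_loading"]] += g_bf[j]
        for j, b in enumerate(self._beh_nodes):
            grad[idx[f"{b.name}_intercept"]] += g_ab[j]
            grad[idx[f"{b.name}_loading"]] += g_bb[j]
        if has_cat:
            grad[idx["histology_squamous_intercept"]] += g_cat[0]
            grad[idx["histology_squamous_loading"]] += g_cat[1]
            grad[idx["histology_other_intercept"]] += g_cat[2]
            grad[idx["histology_other_loading"]] += g_cat[3]
        if treat_in_kernel:
            grad[idx["treatment_intercept"]] += g_scalars[1]
            if d.treat_on_fitness:
                grad[idx["treatment_fitness"]] += g_scalars[2]
            for j, c in enumerate(d.treatment_covs):
                grad[idx[f"treatment_{c}"]] += float(data.Xt[:, j] @ g_base_a)
        grad[idx["outcome_intercept"]] += g_e0.sum()
        grad[idx["outcome_treatment"]] += float(data.A @ g_e0)
        for j, c in enumerate(d.outcome_covs):
            grad[idx[f"outcome_{c}"]] += float(data.Xo[:, j] @ g_e0)
        ag = data.A * g_e0
        for j, c in enumerate(d.interaction_covs):
            grad[idx[f"interaction_{c}"]] += float(data.Xi[:, j] @ ag)
        if d.out_on_fitness:
            grad[idx["outcome_fitness"]] += g_cf.sum()
        if d.interaction_fitness:
            grad[idx["interaction_fitness"]] += float(data.A @ g_cf)
        if d.out_on_behavior:
            grad[idx["outcome_behavior"]] += g_scalars[3]
        grad[idx["weibull_shape"]] += g_scalars[4]
        if d.has_fitness and d.fitness_cause:
            grad[idx["alpha"]] += g_scalars[0]
        return float(ll) + ll_const, grad

    def loglik_and_grad_numpy(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Reference numpy implementation (the kernel is verified against
        this path in the test suite)."""
        d, data, idx = self.design, self.data, self.idx
        n = data.n
        grad = np.zeros(self.n_params)
        g = lambda name: theta[idx[name]]

        # fitness axis
        m = g("alpha") * data.age if (d.has_fitness and d.fitness_cause) else np.zeros(n)
        uf = m[:, None] + self.zf[None, :]  # (n, Qf)
        Qf, Qb = len(self.zf), len(self.zb)
        Lf = np.zeros((n, Qf))
        Lb = np.zeros((n, Qb))
        ll_const = 0.0

        fit_scores: list[tuple[str, int, np.ndarray]] = []  # (name, sign, score) on (n,Qf)
        beh_scores: list[tuple[str, int, np.ndarray]] = []  # on (n,Qb)

        for bn in d.binary_nodes:
            y = data.y_binary[bn.name]
            a = g(f"{bn.name}_intercept")
            if bn.latent == "fitness":
                eta = a + bn.sign * g(f"{bn.name}_loading") * uf
                Lf += y[:, None] * eta - softplus(eta)
                fit_scores.append((bn.name, bn.sign, y[:, None] - sigmoid(eta)))
            elif bn.latent == "behavior":
                eta = a + bn.sign * g(f"{bn.name}_loading") * self.zb  # (Qb,)
                Lb += y[:, None] * eta[None, :] - softplus(eta)[None, :]
                beh_scores.append((bn.name, bn.sign, y[:, None] - sigmoid(eta)[None, :]))
            else:
                s = y - sigmoid(a)
                ll_const += float(np.sum(y * a - softplus(a)))
                grad[idx[f"{bn.name}_intercept"]] += s.sum()

        cat_scores: list[tuple[str, np.ndarray]] = []
        if d.categorical is not None:
            levels = HISTOLOGY_LEVELS[1:]
            if d.categorical_latent:
                etas = [
                    g(f"histology_{lv}_intercept") + g(f"histology_{lv}_loading") * self.zb
                    for lv in levels
                ]  # each (Qb,)
                stacked = np.vstack([np.zeros(Qb)] + etas)  # (3, Qb)
                mx = stacked.max(0)
                logz = mx + np.log(np.exp(stacked - mx).sum(0))
                probs = np.exp(stacked - logz)  # (3, Qb)
                onehot = self._onehot  # (n, 3)
                Lb += onehot @ (stacked - logz)
                for j, lv in enumerate(levels, start=1):
                    cat_scores.append((lv, onehot[:, j : j + 1] - probs[j][None, :]))
            else:
                etas = np.array([g(f"histology_{lv}_intercept") for lv in levels])
                full = np.concatenate([[0.0], etas])
                logz = np.logaddexp.reduce(full)
                probs = np.exp(full - logz)
                onehot = self._onehot
                ll_const += float((onehot @ (full - logz)).sum())
                for j, lv in enumerate(levels, start=1):
                    grad[idx[f"histology_{lv}_intercept"]] += float(
                        (onehot[:, j] - probs[j]).sum()
                    )

        # treatment
        A = data.A
        base_a = (
            g("treatment_intercept") + data.Xt @ theta[self._i_tcovs]
            if d.treatment_covs
            else np.full(n, g("treatment_intercept"))
        )
        treat_latent = d.treat_on_fitness or d.extra_confounder is not None
        sA = None
        if treat_latent:
            eta_a = base_a[:, None] + self.u2[None, :] * (
                d.extra_confounder[0] if d.extra_confounder else 0.0
            )
            if d.treat_on_fitness:
                eta_a = eta_a + g("treatment_fitness") * uf
            Lf += A[:, None] * eta_a - softplus(eta_a)
            sA = A[:, None] - sigmoid(eta_a)
        else:
            ll_const += float(np.sum(A * base_a - softplus(base_a)))
            s0 = A - sigmoid(base_a)
            grad[idx["treatment_intercept"]] += s0.sum()
            for j, c in enumerate(d.treatment_covs):
                grad[idx[f"treatment_{c}"]] += float(data.Xt[:, j] @ s0)

        # outcome (Weibull proportional hazards)
        k = g("weibull_shape")
        beta_o = theta[self._i_ocovs]
        gamma = theta[self._i_icovs]
        e0 = (
            g("outcome_intercept")
            + g("outcome_treatment") * A
            + (data.Xo @ beta_o if d.outcome_covs else 0.0)
            + A * (data.Xi @ gamma if d.interaction_covs else 0.0)
        )
        cf = np.zeros(n)
        if d.out_on_fitness:
            cf += g("outcome_fitness")
        if d.interaction_fitness:
            cf += g("interaction_fitness") * A
        ef = cf[:, None] * uf
        if d.extra_confounder is not None:
            ef = ef + d.extra_confounder[1] * self.u2[None, :]
        eb = (g("outcome_behavior") * self.zb) if d.out_on_behavior else np.zeros(Qb)

        with np.errstate(over="ignore", invalid="ignore"):
            log_h0 = k * data.log_time + e0
            H0 = np.exp(log_h0)
            Ef = np.exp(ef)
            Eb = np.exp(eb)
            const = data.event * (np.log(k) + (k - 1.0) * data.log_time + e0)

            Af = Lf + data.event[:, None] * ef
            Bb = Lb + data.event[:, None] * eb[None, :]
            # clip the cumulative hazard: overflowing cells get responsibility
            # zero anyway, and inf * 0 would poison the gradient with NaNs
            Lam = np.minimum(
                H0[:, None, None] * Ef[:, :, None] * Eb[None, None, :], 1e300
            )
            G = Af[:, :, None] + Bb[:, None, :] - Lam
            Gmax = G.max(axis=(1, 2))
            W = (self.wf[None, :, None] * self.wb[None, None, :]) * np.exp(
                G - Gmax[:, None, None]
            )
            Z = W.sum(axis=(1, 2))
            logz_i = const + Gmax + np.log(Z)

        if not np.all(np.isfinite(logz_i)):
            return -np.inf, grad

        ll = ll_const + float(logz_i.sum())

        # --- gradients through the quadrature responsibilities ----------
        R = W / Z[:, None, None]
        Rf = R.sum(2)
        Rb = R.sum(1)
        RLam = R * Lam
        ELam = RLam.sum(axis=(1, 2))
        ELam_f = RLam.sum(2)
        ELam_b = RLam.sum(1)
        resid = data.event - ELam
        Euf = (Rf * uf).sum(1)
        ELam_uf = (ELam_f * uf).sum(1)

        grad[idx["outcome_intercept"]] += resid.sum()
        grad[idx["outcome_treatment"]] += float(A @ resid)
        for j, c in enumerate(d.outcome_covs):
            grad[idx[f"outcome_{c}"]] += float(data.Xo[:, j] @ resid)
        Ar = A * resid
        for j, c in enumerate(d.interaction_covs):
            grad[idx[f"interaction_{c}"]] += float(data.Xi[:, j] @ Ar)
        if d.out_on_fitness:
            grad[idx["outcome_fitness"]] += float((data.event * Euf - ELam_uf).sum())
        if d.interaction_fitness:
            grad[idx["interaction_fitness"]] += float(
                (A * (data.event * Euf - ELam_uf)).sum()
            )
        if d.out_on_behavior:
            Eub = Rb @ self.zb
            ELam_ub = ELam_b @ self.zb
            grad[idx["outcome_behavior"]] += float((data.event * Eub - ELam_ub).sum())
        grad[idx["weibull_shape"]] += float(
            (data.event * (1.0 / k + data.log_time) - ELam * data.log_time).sum()
        )

        sfit = np.zeros((n, Qf))  # d loglik / d u_f, for the alpha chain rule
        for name, sign, s in fit_scores:
            rs = Rf * s
            grad[idx[f"{name}_intercept"]] += rs.sum()
            grad[idx[f"{name}_loading"]] += sign * float((rs * uf).sum())
            sfit += sign * theta[idx[f"{name}_loading"]] * s
        if treat_latent and sA is not None:
            rsa = Rf * sA
            grad[idx["treatment_intercept"]] += rsa.sum()
            row = rsa.sum(1)
            for j, c in enumerate(d.treatment_covs):
                grad[idx[f"treatment_{c}"]] += float(data.Xt[:, j] @ row)
            if d.treat_on_fitness:
                grad[idx["treatment_fitness"]] += float((rsa * uf).sum())
                sfit += g("treatment_fitness") * sA

        for name, sign, s in beh_scores:
            rs = Rb * s
            grad[idx[f"{name}_intercept"]] += rs.sum()
            grad[idx[f"{name}_loading"]] += sign * float((rs * self.zb[None, :]).sum())
        for lv, s in cat_scores:
            rs = Rb * s
            grad[idx[f"histology_{lv}_intercept"]] += rs.sum()
            grad[idx[f"histology_{lv}_loading"]] += float((rs * self.zb[None, :]).sum())

        if d.has_fitness and d.fitness_cause:
            total = (Rf * sfit).sum(1) + cf * resid
            grad[idx["alpha"]] += float(data.age @ total)

        return ll, grad

    # ------------------------------------------------------------------
    def logpost_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        """Log-posterior and gradient on the unconstrained scale (positive
        parameters sampled through log transforms, Jacobian included)."""
        if not np.all(np.isfinite(x)):
            return -np.inf, np.zeros(self.n_params)
        with np.errstate(over="ignore"):
            theta = self.to_natural(x)
        if not np.all(np.isfinite(theta)):
            return -np.inf, np.zeros(self.n_params)
        ll, grad_theta = self.loglik_and_grad(theta)
        if not np.isfinite(ll):
            return -np.inf, np.zeros(self.n_params)
        # priors: Normal(0, s^2) unconstrained, Half-Normal(s) positive
        lp = ll - 0.5 * float(np.sum((theta / self.prior_scale) ** 2))
        grad_theta = grad_theta - theta / self.prior_scale**2
        grad_x = np.where(self.positive, grad_theta * theta + 1.0, grad_theta)
        lp += float(x[self.positive].sum())  # log-Jacobian of exp
        return lp, grad_x

    def logpost(self, x: np.ndarray) -> float:
        return self.logpost_and_grad(x)[0]

    # ------------------------------------------------------------------
    def fitness_posterior(
        self,
        theta: np.ndarray,
        data: CohortData | None = None,
        include_treatment: bool = False,
        exclude: tuple[str, ...] = (),
    ) -> tuple[np.ndarray, np.ndarray]:
        """Quadrature posterior of U_f given age and the fitness proxies
        (optionally also the treatment decision), for one parameter draw.
        ``exclude`` drops named proxies from the conditioning set (used for
        held-out prediction of that proxy).

        Returns ``(uf, r)``: node values and normalized weights, (n, Qf).
        """
        d, idx = self.design, self.idx
        data = data or self.data
        n = data.n
        g = lambda name: theta[idx[name]]
        m = g("alpha") * data.age if (d.has_fitness and d.fitness_cause) else np.zeros(n)
        uf = m[:, None] + self.zf[None, :]
        L = np.zeros((n, len(self.zf)))
        for bn in d.binary_nodes:
            if bn.latent != "fitness" or bn.name in exclude:
                continue
            y = data.y_binary[bn.name]
            eta = g(f"{bn.name}_intercept") + bn.sign * g(f"{bn.name}_loading") * uf
            L += y[:, None] * eta - softplus(eta)
        if include_treatment and d.treat_on_fitness:
            base = g("treatment_intercept") + (
                data.Xt @ theta[[idx[f"treatment_{c}"] for c in d.treatment_covs]]
                if d.treatment_covs
                else 0.0
            )
            eta = base[:, None] + g("treatment_fitness") * uf
            L += data.A[:, None] * eta - softplus(eta)
        L += np.log(self.wf)[None, :]
        L -= L.max(1, keepdims=True)
        r = np.exp(L)
        r /= r.sum(1, keepdims=True)
        return uf, r

    def behavior_posterior(
        self,
        theta: np.ndarray,
        data: CohortData | None = None,
        exclude: tuple[str, ...] = (),
    ) -> tuple[np.ndarray, np.ndarray]:
        """Quadrature posterior of U_b given the behavior proxies."""
        d, idx = self.design, self.idx
        data = data or self.data
        n = data.n
        g = lambda name: theta[idx[name]]
        Qb = len(self.zb)
        L = np.zeros((n, Qb))
        for bn in d.binary_nodes:
            if bn.latent != "behavior" or bn.name in exclude:
                continue
            y = data.y_binary[bn.name]
            eta = g(f"{bn.name}_intercept") + bn.sign * g(f"{bn.name}_loading") * self.zb
            L += y[:, None] * eta[None, :] - softplus(eta)[None, :]
        if d.categorical is not None and d.categorical_latent:
            levels = HISTOLOGY_LEVELS[1:]
            etas = [
                g(f"histology_{lv}_intercept") + g(f"histology_{lv}_loading") * self.zb
                for lv in levels
            ]
            stacked = np.vstack([np.zeros(Qb)] + etas)
            mx = stacked.max(0)
            logz = mx + np.log(np.exp(stacked - mx).sum(0))
            onehot = np.eye(len(HISTOLOGY_LEVELS))[data.y_cat]
            L += onehot @ (stacked - logz)
        L += np.log(self.wb)[None, :]
        L -= L.max(1, keepdims=True)
        r = np.exp(L)
        r /= r.sum(1, keepdims=True)
        return np.broadcast_to(self.zb, (n, Qb)), r

    def propensity(self, theta: np.ndarray, data: CohortData | None = None) -> np.ndarray:
        """P(treatment = 1 | pre-treatment variables), the latent fitness
        marginalized over its proxy posterior."""
        d, idx = self.design, self.idx
        data = data or self.data
        g = lambda name: theta[idx[name]]
        base = g("treatment_intercept") + (
            data.Xt @ theta[[idx[f"treatment_{c}"] for c in d.treatment_covs]]
            if d.treatment_covs
            else 0.0
        )
        if not d.treat_on_fitness:
            return sigmoid(np.broadcast_to(base, (data.n,)))
        uf, r = self.fitness_posterior(theta, data, include_treatment=False)
        return (r * sigmoid(base[:, None] + g("treatment_fitness") * uf)).sum(1)


def map_estimate(
    model: CollapsedModel,
    x0: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    maxiter: int = 500,
) -> np.ndarray:
    """Posterior mode on the unconstrained scale (L-BFGS with analytic
    gradients); used for fold fits in cross-validation and for warm starts."""
    if x0 is None:
        rng = rng or np.random.default_rng(0)
        x0 = model.initial_vector(rng, jitter=0.01)

    def objective(x):
        lp, grad = model.logpost_and_grad(x)
        if not np.isfinite(lp):
            return 1e10, np.zeros_like(x)
        return -lp, -grad

    res = minimize(objective, x0, jac=True, method="L-BFGS-B", options={"maxiter": maxiter})
    return res.x
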