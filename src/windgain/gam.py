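"""Penalized additive model of daily mass gain with a circular wind smoother.

The model, fitted by penalized least squares with a Gaussian response, is

    gain_d = β0 + β_season + β_stage + β_s · speed_d
             + f1(dir_d) + f2(dir_d) · speed_d + ε_d

where ``dir`` is the meteorological wind direction in degrees (a circular
covariate: 0° ≡ 360°) and both smooths f1 and f2 are *cyclic cubic
regression splines* — piecewise cubics through evenly spaced knots on the
circle, constrained so the function and its first two derivatives match at
the 0/360 seam. f2 enters as a varying-coefficient term: the slope of gain
on wind speed varies smoothly (and periodically) with wind direction, which
is the direction × speed interaction.

Each smooth has a wiggliness penalty λ ∫ f''(x)² dx over the circle and a
sum-to-zero identifiability constraint over the observed directions (the
intercept absorbs the mean; the linear speed term absorbs the constant part
of f2). Smoothing parameters are chosen by Generalized Cross-Validation,

    GCV(λ) = n · RSS(λ) / (n − edf(λ))²,

minimised coordinate-wise over log λ (coarse grid, then golden-section
refinement). ``λ = inf`` is handled as the exact limit: the smooth is
dropped from the design, so the infinite-smoothing fit coincides exactly
with the parametric-only least-squares fit. Effective degrees of freedom
(EDF) per term are the trace of the term's block of F = (X'X + S_λ)⁻¹ X'X,
and "deviance explained" is the Gaussian 1 − RSS/TSS, in percent.

Per-term p-values use an EDF-based approximate Wald/F test and should be
read as approximate, as is conventional for penalized smooths.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats as sps

__all__ = ["CyclicSpline", "CircularGainGAM", "CircularGAMResults"]

_PERIOD = 360.0


class CyclicSpline:
    """Cyclic cubic regression spline basis on [0, 360) with ``k`` knots.

    The ``k`` basis coefficients are the function values at ``k`` evenly
    spaced knots; the cubic interpolant between them is the unique periodic
    natural cubic spline. ``penalty()`` is the exact integrated squared
    second derivative as a quadratic form in the coefficients, a symmetric
    positive semi-definite matrix whose null space is the constant function.
    """

    def __init__(self, k: int = 8):
        if k < 4:
            raise ValueError("a cyclic cubic spline needs k >= 4 knots")
        self.k = int(k)
        self.knots = np.linspace(0.0, _PERIOD, self.k, endpoint=False)
        self._h = np.full(self.k, _PERIOD / self.k)
        self._BinvD = self._compute_binv_d()

    def _compute_binv_d(self) -> np.ndarray:
        k, h = self.k, self._h
        B = np.zeros((k, k))
        D = np.zeros((k, k))
        for i in range(k):
            ip = (i + 1) % k
            im = (i - 1) % k
            B[i, i] = (h[im] + h[i]) / 3.0
            B[i, ip] += h[i] / 6.0
            B[i, im] += h[im] / 6.0
            D[i, i] = -(1.0 / h[im] + 1.0 / h[i])
            D[i, ip] += 1.0 / h[i]
            D[i, im] += 1.0 / h[im]
        self._B = B
        self._D = D
        return sla.solve(B, D, assume_a="pos")

    def basis(self, x) -> np.ndarray:
        """Design matrix rows evaluating the spline at ``x`` (degrees).

        Exactly periodic: rows for 0 and 360 are identical because ``x`` is
        reduced mod 360 before evaluation.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        xm = np.mod(x, _PERIOD)
        j = np.clip((xm // (_PERIOD / self.k)).astype(int), 0, self.k - 1)
        xj = self.knots[j]
        h = self._h[j]
        t_right = xj + h - xm  # distance to the interval's right knot
        t_left = xm - xj
        a = np.zeros((x.size, self.k))
        c = np.zeros((x.size, self.k))
        rows = np.arange(x.size)
        jp = (j + 1) % self.k
        a[rows, j] += t_right / h
        a[rows, jp] += t_left / h
        c[rows, j] += (t_right**3 / h - h * t_right) / 6.0
        c[rows, jp] += (t_left**3 / h - h * t_left) / 6.0
        return a + c @ self._BinvD

    def penalty(self) -> np.ndarray:
        """∫₀³⁶⁰ f''(x)² dx as a quadratic form (k × k, PSD, constants → 0)."""
        S = self._D.T @ sla.solve(self._B, self._D, assume_a="pos")
        return (S + S.T) / 2.0


def _nullspace_transform(c: np.ndarray) -> np.ndarray:
    """Orthonormal basis Z of the null space of the 1 × m constraint c."""
    _, _, vt = np.linalg.svd(c.reshape(1, -1), full_matrices=True)
    return vt[1:].T  # m × (m-1)


class CircularGainGAM:
    """Additive model of daily foraging mass gain on wind and calendar terms.

    Parameters
    ----------
    gain
        Response: daily pooled mass gain (g), one value per day.
    speed, direction
        Daily mean wind speed (m/s) and meteorological direction (degrees,
        the bearing the wind comes from).
    season, stage
        Optional categorical fixed effects (breeding season, chick-rearing
        stage); dropped from the design when absent or single-level.
    k
        Knots per cyclic smooth (default 8). Must not exceed the number of
        distinct observed directions.
    direction_smooth, interaction
        Flags to drop f1(direction) or the f2(direction)·speed
        varying-coefficient interaction from the design.

    Rows with a missing response or covariate are deleted listwise;
    ``n_dropped`` records how many.
    """

    def __init__(
        self,
        gain,
        speed,
        direction,
        season=None,
        stage=None,
        k: int = 8,
        direction_smooth: bool = True,
        interaction: bool = True,
    ):
        gain = np.asarray(gain, dtype=float)
        speed = np.asarray(speed, dtype=float)
        direction = np.asarray(direction, dtype=float)
        n0 = gain.size
        cols = [gain, speed, direction]
        season = None if season is None else np.asarray(season, dtype=object)
        stage = None if stage is None else np.asarray(stage, dtype=object)
        keep = np.isfinite(gain) & np.isfinite(speed) & np.isfinite(direction)
        if season is not None:
            keep &= pd.notna(season)
        if stage is not None:
            keep &= pd.notna(stage)
        self.n_dropped = int(n0 - keep.sum())
        self.gain = gain[keep]
        self.speed = speed[keep]
        self.direction = np.mod(direction[keep], _PERIOD)
        self.season = season[keep] if season is not None else None
        self.stage = stage[keep] if stage is not None else None
        self.nobs = int(keep.sum())
        if self.nobs < 20:
            raise ValueError(f"need at least 20 complete days, have {self.nobs}")
        n_distinct = np.unique(np.round(self.direction, 9)).size
        if k > n_distinct:
            raise ValueError(
                f"k={k} exceeds the {n_distinct} distinct observed directions"
            )
        self.k = int(k)
        self.spline = CyclicSpline(self.k)
        self._with_f1 = bool(direction_smooth)
        self._with_f2 = bool(interaction)
        self._build_design()

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str = "gain_g",
        speed: str = "speed_ms",
        direction: str = "direction_deg",
        season: str | None = "season",
        stage: str | None = "stage",
        **kwargs,
    ) -> "CircularGainGAM":
        def col(name):
            return data[name].to_numpy() if name and name in data.columns else None

        return cls(
            data[response].to_numpy(),
            data[speed].to_numpy(),
            data[direction].to_numpy(),
            season=col(season),
            stage=col(stage),
            **kwargs,
        )

    # -- design ------------------------------------------------------------

    def _build_design(self):
        n = self.nobs
        blocks: list[np.ndarray] = [np.ones((n, 1))]
        names: list[str] = ["intercept"]
        slices: dict[str, slice] = {"intercept": slice(0, 1)}
        self.season_levels: tuple = ()
        self.stage_levels: tuple = ()
        pos = 1

        def add_factor(values, label):
            nonlocal pos
            levels = tuple(pd.unique(values))
            if len(levels) < 2:
                return levels
            dummies = np.column_stack(
                [(values == lv).astype(float) for lv in levels[1:]]
            )
            blocks.append(dummies)
            names.append(label)
            slices[label] = slice(pos, pos + dummies.shape[1])
            pos += dummies.shape[1]
            return levels

        if self.season is not None:
            self.season_levels = add_factor(self.season, "season")
        if self.stage is not None:
            self.stage_levels = add_factor(self.stage, "stage")

        blocks.append(self.speed.reshape(-1, 1))
        names.append("speed")
        slices["speed"] = slice(pos, pos + 1)
        pos += 1

        Xc = self.spline.basis(self.direction)  # n × k
        S0 = self.spline.penalty()
        # Sum-to-zero over the observed directions, for both smooths: removes
        # the constant (absorbed by the intercept, and for f2 by the linear
        # speed term).
        self._Z = _nullspace_transform(Xc.sum(axis=0))
        Sz = self._Z.T @ S0 @ self._Z
        self.smooth_names: list[str] = []
        self._penalties: dict[str, np.ndarray] = {}
        if self._with_f1:
            blocks.append(Xc @ self._Z)
            names.append("s(direction)")
            slices["s(direction)"] = slice(pos, pos + self.k - 1)
            pos += self.k - 1
            self.smooth_names.append("s(direction)")
            self._penalties["s(direction)"] = Sz
        if self._with_f2:
            blocks.append(self.speed[:, None] * (Xc @ self._Z))
            names.append("s(direction):speed")
            slices["s(direction):speed"] = slice(pos, pos + self.k - 1)
            pos += self.k - 1
            self.smooth_names.append("s(direction):speed")
            self._penalties["s(direction):speed"] = Sz

        self.exog = np.hstack(blocks)
        self.term_names = names
        self.term_slices = slices
        self.nparams = pos
        # Structural collinearity among the parametric terms (e.g. a factor
        # duplicating another) is an error; near-deficiency involving the
        # smooth blocks (an unobserved direction arc) is handled by the
        # wiggliness penalty and only recorded.
        n_param = slices["speed"].stop
        Xp = self.exog[:, :n_param]
        if np.linalg.matrix_rank(Xp) < n_param:
            parametric = [t for t in names if t not in self.smooth_names]
            raise ValueError(
                f"parametric design is rank deficient; collinear terms among {parametric}"
            )
        sv = np.linalg.svd(self.exog, compute_uv=False)
        self.design_deficient = bool(sv[-1] <= sv[0] * 1e-10)

    def _embedded_penalties(self) -> dict[str, np.ndarray]:
        out = {}
        for name, Sz in self._penalties.items():
            S = np.zeros((self.nparams, self.nparams))
            sl = self.term_slices[name]
            S[sl, sl] = Sz
            out[name] = S
        return out

    # -- fitting -----------------------------------------------------------

    def _solve(self, lam: dict[str, float]):
        """Penalized normal-equations solve at fixed λ (inf = drop block)."""
        active = np.ones(self.nparams, dtype=bool)
        for name in self.smooth_names:
            if np.isinf(lam[name]):
                active[self.term_slices[name]] = False
        X = self.exog[:, active]
        XtX = X.T @ X
        Xty = X.T @ self.gain
        A = XtX.copy()
        Sfull = self._embedded_penalties()
        for name in self.smooth_names:
            lv = lam[name]
            if np.isfinite(lv) and lv != 0.0:
                A += lv * Sfull[name][np.ix_(active, active)]
        try:
            cf = sla.cho_factor(A)
            Ainv_a = sla.cho_solve(cf, np.eye(A.shape[0]))
        except np.linalg.LinAlgError:
            Ainv_a = np.linalg.pinv(A)
        beta_a = Ainv_a @ Xty
        F_a = Ainv_a @ XtX
        beta = np.zeros(self.nparams)
        beta[active] = beta_a
        fitted = X @ beta_a
        resid = self.gain - fitted
        rss = float(resid @ resid)
        edf_diag = np.zeros(self.nparams)
        edf_diag[active] = np.diag(F_a)
        Ainv_full = np.zeros((self.nparams, self.nparams))
        Ainv_full[np.ix_(active, active)] = Ainv_a
        return {
            "beta": beta,
            "fitted": fitted,
            "resid": resid,
            "rss": rss,
            "edf_diag": edf_diag,
            "edf_total": float(edf_diag.sum()),
            "Ainv": Ainv_full,
            "active": active,
        }

    def _gcv(self, sol) -> float:
        n = self.nobs
        denom = n - sol["edf_total"]
        if denom <= 0:
            return np.inf
        return n * sol["rss"] / denom**2

    def fit(
        self,
        lam: dict[str, float] | tuple | float | None = None,
        method: str = "gcv",
        log_lam_bounds: tuple[float, float] = (-5.0, 12.0),
        tol: float = 1e-6,
        max_sweeps: int = 10,
    ) -> "CircularGAMResults":
        """Fit the model.

        With ``lam`` given (a mapping smooth-name → λ, a tuple in smooth
        order, or one scalar for all smooths; ``0``, finite, or ``inf`` per
        smooth), the penalized least-squares solution at those fixed λ is
        returned. Otherwise smoothing parameters are selected by minimising
        GCV coordinate-wise on log10 λ: a coarse grid sweep per smooth
        followed by golden-section refinement, iterated to convergence of the
        score. A selection ending on the search boundary is flagged on the
        results (``gcv_bound_hit``).
        """
        if lam is not None:
            lam_map = self._lam_map(lam)
            sol = self._solve(lam_map)
            return CircularGAMResults(self, lam_map, sol, gcv_score=self._gcv(sol))
        if method != "gcv":
            raise ValueError(f"unknown smoothing selection method {method!r}")
        if not self.smooth_names:
            lam_map = {}
            sol = self._solve(lam_map)
            return CircularGAMResults(self, lam_map, sol, gcv_score=self._gcv(sol))

        lo, hi = log_lam_bounds
        cache: dict[tuple, tuple[float, dict]] = {}

        def score_at(loglams: dict[str, float]):
            key = tuple(round(loglams[s], 12) for s in self.smooth_names)
            if key not in cache:
                lam_map = {s: 10.0 ** loglams[s] for s in self.smooth_names}
                sol = self._solve(lam_map)
                cache[key] = (self._gcv(sol), sol)
            return cache[key][0]

        current = {s: 2.0 for s in self.smooth_names}
        grid = np.arange(lo, hi + 0.5, 1.0)
        last = np.inf
        for _ in range(max_sweeps):
            for s in self.smooth_names:
                best = min(grid, key=lambda g: score_at({**current, s: g}))
                a, b = max(lo, best - 1.0), min(hi, best + 1.0)
                current[s] = _golden_min(
                    lambda g: score_at({**current, s: g}), a, b, tol=1e-4
                )
            now = score_at(current)
            if abs(last - now) <= tol * (1.0 + abs(now)):
                break
            last = now
        # The reported optimum is the best point actually evaluated, so the
        # selected score is <= every grid candidate by construction.
        best_key = min(cache, key=lambda kk: cache[kk][0])
        best_log = dict(zip(self.smooth_names, best_key))
        gcv_score, sol = cache[best_key]
        lam_map = {s: 10.0 ** best_log[s] for s in self.smooth_names}
        bound_hit = any(
            abs(best_log[s] - lo) < 1e-6 or abs(best_log[s] - hi) < 1e-6
            for s in self.smooth_names
        )
        return CircularGAMResults(
            self, lam_map, sol, gcv_score=gcv_score, gcv_bound_hit=bound_hit
        )

    def _lam_map(self, lam) -> dict[str, float]:
        if isinstance(lam, dict):
            missing = [s for s in self.smooth_names if s not in lam]
            if missing:
                raise ValueError(f"lam missing smooths {missing}")
            return {s: float(lam[s]) for s in self.smooth_names}
        if np.isscalar(lam):
            return {s: float(lam) for s in self.smooth_names}
        lam = tuple(lam)
        if len(lam) != len(self.smooth_names):
            raise ValueError(
                f"expected {len(self.smooth_names)} smoothing parameters, got {len(lam)}"
            )
        return dict(zip(self.smooth_names, (float(v) for v in lam)))


def _golden_min(f, a, b, tol=1e-4):
    """Golden-section minimisation of f on [a, b]."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return c if fc < fd else d


class CircularGAMResults:
    """Fit results: coefficients, λ, EDFs, deviance explained, predictions."""

    def __init__(self, model: CircularGainGAM, lam, sol, gcv_score=np.nan, gcv_bound_hit=False):
        self.model = model
        self.smoothing_params = dict(lam)
        self.params = sol["beta"]
        self.fittedvalues = sol["fitted"]
        self.resid = sol["resid"]
        self.rss = sol["rss"]
        self._edf_diag = sol["edf_diag"]
        self.edf_total = sol["edf_total"]
        self._Ainv = sol["Ainv"]
        self._active = sol["active"]
        self.gcv_score = float(gcv_score)
        self.gcv_bound_hit = bool(gcv_bound_hit)
        y = model.gain
        self.tss = float(np.sum((y - y.mean()) ** 2))
        self.nobs = model.nobs
        self.df_resid = self.nobs - self.edf_total
        self.sigma2 = self.rss / self.df_resid if self.df_resid > 0 else np.nan

    # -- scalar summaries --------------------------------------------------

    @property
    def deviance_explained(self) -> float:
        """Percent of the Gaussian deviance explained: 100 · (1 − RSS/TSS)."""
        if self.tss == 0:
            return np.nan
        return 100.0 * (1.0 - self.rss / self.tss)

    @property
    def bse(self) -> np.ndarray:
        """Frequentist standard errors of the penalized coefficients."""
        XtX = self.model.exog.T @ self.model.exog
        Vf = self.sigma2 * (self._Ainv @ XtX @ self._Ainv)
        return np.sqrt(np.clip(np.diag(Vf), 0.0, None))

    @property
    def edf(self) -> dict[str, float]:
        """Effective degrees of freedom per model term."""
        out = {}
        for name in self.model.term_names:
            sl = self.model.term_slices[name]
            out[name] = float(self._edf_diag[sl].sum())
        return out

    # -- term tests ----------------------------------------------------------

    def term_table(self) -> pd.DataFrame:
        """Per-term EDF/df, approximate F and p (Wald-type for smooths).

        Parametric terms use the frequentist covariance of the penalized
        estimator; smooth terms use the EDF-rank pseudoinverse Wald statistic
        against an F(edf, residual df) reference. Both are approximations —
        exact sampling distributions do not exist once λ is data-selected.
        """
        m = self.model
        XtX = m.exog.T @ m.exog
        Vf = self.sigma2 * (self._Ainv @ XtX @ self._Ainv)  # frequentist
        Vb = self.sigma2 * self._Ainv  # Bayesian
        rows = []
        for name in m.term_names:
            if name == "intercept":
                continue
            sl = m.term_slices[name]
            beta = self.params[sl]
            if name in m.smooth_names:
                edf = float(self._edf_diag[sl].sum())
                F, p = _smooth_wald(beta, Vb[sl, sl], edf, self.df_resid)
                rows.append({"term": name, "edf": edf, "F": F, "p": p})
            else:
                q = sl.stop - sl.start
                V = Vf[sl, sl]
                if not self._active[sl].any() or self.sigma2 != self.sigma2:
                    rows.append({"term": name, "edf": float(q), "F": np.nan, "p": np.nan})
                    continue
                stat = float(beta @ np.linalg.solve(V, beta)) / q
                p = float(sps.f.sf(stat, q, self.df_resid))
                rows.append({"term": name, "edf": float(q), "F": stat, "p": p})
        return pd.DataFrame(rows, columns=["term", "edf", "F", "p"])

    # -- prediction ----------------------------------------------------------

    def _design_for(self, direction, speed, season=None, stage=None) -> np.ndarray:
        m = self.model
        direction = np.atleast_1d(np.asarray(direction, dtype=float))
        speed = np.broadcast_to(
            np.asarray(speed, dtype=float), direction.shape
        ).astype(float)
        n = direction.size
        X = np.zeros((n, m.nparams))
        X[:, m.term_slices["intercept"]] = 1.0
        for label, levels, value in (
            ("season", m.season_levels, season),
            ("stage", m.stage_levels, stage),
        ):
            if label not in m.term_slices:
                continue
            lv = levels[0] if value is None else value
            if lv not in levels:
                raise ValueError(f"unknown {label} level {lv!r} (have {levels})")
            dummies = np.array([(lv == l2) for l2 in levels[1:]], dtype=float)
            X[:, m.term_slices[label]] = dummies
        X[:, m.term_slices["speed"]] = speed.reshape(-1, 1)
        Xc = m.spline.basis(direction) @ m._Z
        if "s(direction)" in m.term_slices:
            X[:, m.term_slices["s(direction)"]] = Xc
        if "s(direction):speed" in m.term_slices:
            X[:, m.term_slices["s(direction):speed"]] = speed[:, None] * Xc
        return X

    def predict(self, direction, speed, season=None, stage=None) -> np.ndarray:
        """Predicted gain at (direction, speed), factors at given/reference levels."""
        return self._design_for(direction, speed, season, stage) @ self.params

    def predict_surface(
        self,
        directions=None,
        speeds=None,
        season=None,
        stage=None,
        direction_tolerance_deg: float = 15.0,
    ) -> pd.DataFrame:
        """Prediction surface over a (direction × speed) grid.

        Defaults: directions every 5° over [0, 360), speeds on 40 points
        from 0 to the maximum observed speed; parametric factors at their
        reference (first) levels, recorded in ``DataFrame.attrs``. Cells are
        flagged ``extrapolated`` when the speed lies outside the observed
        range or no observed direction falls within
        ``direction_tolerance_deg`` of the cell (circular distance).
        """
        m = self.model
        if directions is None:
            directions = np.arange(0.0, _PERIOD, 5.0)
        else:
            directions = np.asarray(directions, dtype=float)
        if speeds is None:
            speeds = np.linspace(0.0, float(m.speed.max()), 40)
        else:
            speeds = np.asarray(speeds, dtype=float)
        if directions.size == 0 or speeds.size == 0:
            raise ValueError("empty prediction grid")
        D, S = np.meshgrid(directions, speeds)
        pred = self.predict(D.ravel(), S.ravel(), season=season, stage=stage)
        obs_dir = m.direction
        dgrid = np.mod(D.ravel(), _PERIOD)
        circ = np.abs(dgrid[:, None] - obs_dir[None, :])
        circ = np.minimum(circ, _PERIOD - circ)
        dir_gap = circ.min(axis=1)
        s_lo, s_hi = float(m.speed.min()), float(m.speed.max())
        extrap = (
            (S.ravel() < s_lo)
            | (S.ravel() > s_hi)
            | (dir_gap > direction_tolerance_deg)
        )
        out = pd.DataFrame(
            {
                "direction_deg": D.ravel(),
                "speed_ms": S.ravel(),
                "gain_g": pred,
                "extrapolated": extrap,
            }
        )
        out.attrs["reference_levels"] = {
            "season": (season if season is not None else (m.season_levels[0] if m.season_levels else None)),
            "stage": (stage if stage is not None else (m.stage_levels[0] if m.stage_levels else None)),
        }
        return out

    def plot_surface(self, ax=None, **surface_kwargs):
        """Colour-map of the prediction surface (speed × direction)."""
        import matplotlib.pyplot as plt

        surf = self.predict_surface(**surface_kwargs)
        dirs = np.sort(surf["direction_deg"].unique())
        spds = np.sort(surf["speed_ms"].unique())
        Z = (
            surf.pivot(index="speed_ms", columns="direction_deg", values="gain_g")
            .loc[spds, dirs]
            .to_numpy()
        )
        if ax is None:
            _, ax = plt.subplots()
        mesh = ax.pcolormesh(dirs, spds, Z, shading="nearest", cmap="RdYlBu")
        ax.set_xlabel("wind direction (° from)")
        ax.set_ylabel("wind speed (m/s)")
        ax.figure.colorbar(mesh, ax=ax, label="predicted daily mass gain (g)")
        return ax

    # -- reporting -----------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Circular-smoother additive model of daily foraging mass gain",
            f"n = {self.nobs} days ({self.model.n_dropped} dropped incomplete), "
            f"k = {self.model.k} knots per smooth",
            f"deviance explained = {self.deviance_explained:.1f}%   "
            f"GCV = {self.gcv_score:.4g}   sigma = {np.sqrt(self.sigma2):.1f} g",
        ]
        if self.gcv_bound_hit:
            lines.append("warning: GCV optimum at the lambda search bound")
        lam = ", ".join(f"{s}: {v:.4g}" for s, v in self.smoothing_params.items())
        if lam:
            lines.append(f"lambda ({lam})")
        tab = self.term_table()
        lines.append("")
        lines.append(f"{'term':<22}{'edf':>8}{'F':>10}{'p':>10}")
        for _, r in tab.iterrows():
            pstr = "<0.001" if r["p"] < 0.001 else f"{r['p']:.3f}"
            lines.append(f"{r['term']:<22}{r['edf']:>8.2f}{r['F']:>10.3f}{pstr:>10}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serialisable fit summary (for manifests and reports)."""
        tab = self.term_table()
        return {
            "n": self.nobs,
            "n_dropped": self.model.n_dropped,
            "k": self.model.k,
            "smoothing_params": {s: float(v) for s, v in self.smoothing_params.items()},
            "edf": {t: float(v) for t, v in self.edf.items()},
            "deviance_explained_pct": float(self.deviance_explained),
            "gcv": self.gcv_score,
            "gcv_bound_hit": self.gcv_bound_hit,
            "sigma_g": float(np.sqrt(self.sigma2)),
            "terms": tab.to_dict(orient="records"),
            "coefficients": self.params.tolist(),
        }


def _smooth_wald(beta, V, edf, df_resid):
    """EDF-rank pseudoinverse Wald test for one smooth term.

    Eigen-truncates the Bayesian covariance block at rank ⌊edf⌋ with a
    fractional weight on the next eigendirection, forms
    F = βᵀṼ⁻β / edf and refers it to F(edf, df_resid) (fractional degrees
    of freedom are fine for the F distribution).
    """
    if edf < 1e-3:
        return 0.0, 1.0
    w, U = np.linalg.eigh((V + V.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, U = w[order], U[:, order]
    w = np.clip(w, 1e-300, None)
    k0 = int(np.floor(edf))
    frac = edf - k0
    q = len(w)
    M = np.zeros_like(V)
    for i in range(min(k0, q)):
        M += np.outer(U[:, i], U[:, i]) / w[i]
    if k0 < q and frac > 0:
        M += frac * np.outer(U[:, k0], U[:, k0]) / w[k0]
    stat = float(beta @ M @ beta) / edf
    p = float(sps.f.sf(stat, edf, max(df_resid, 1e-8)))
    return stat, p
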