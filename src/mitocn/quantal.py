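"""Quantal nucleoid-intensity estimation and mCN conversion.

mtDNA nucleoids carry small integer numbers of genome copies, so the
integrated intensities of anti-dsDNA puncta are quantized: a punctum with k
copies measures k·q plus noise, where q is the single-copy (quantal)
intensity.  Pooling all puncta of one staining batch, the intensity
distribution is fitted with a 10-component Gaussian mixture whose component
means are constrained to integer multiples of q, under the identifying
assumption that the most abundant puncta are single-copy nucleoids (the
first component carries the largest weight).  The per-cell mitochondrial DNA
copy number is then the cell's summed punctum intensity divided by q.

The model/fit API follows the statsmodels convention: build a
:class:`QuantalIntensityModel` from the pooled intensities, call
:meth:`~QuantalIntensityModel.fit`, and read estimates off the returned
:class:`QuantalFit` results object.

Model
-----
With component weights w_1..w_K (simplex) and per-component spread
sigma_k = sigma * sqrt(k) (copy variances add), the punctum intensity density is

    p(x) = sum_k w_k * N(x; k q, sigma^2 k)

The default fit minimizes the weighted least-squares distance between this
mixture (integrated over histogram bins, Freedman-Diaconis widths) and the
observed histogram; for fixed (q, sigma) the optimal non-negative weights
are a non-negative least-squares solve, and (q, sigma) are optimized in log
space from a multi-start grid of q values between the 5th percentile and the
mode of the intensities, which avoids the k-aliasing local optimum at q/2.
A raw-sample EM fit with the same mean constraint is available with
``method="em"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp, ndtr

__all__ = ["QuantalIntensityModel", "QuantalFit", "estimate_mcn",
           "normalize_to_reference"]


@dataclass
class QuantalFit:
    """Results of a quantal mixture fit.

    ``q`` is the single-copy nucleoid intensity (a.u.), ``weights`` the
    mixture weights over copy numbers 1..K (sum to 1), ``sigma`` the
    single-copy noise scale (a.u.), ``resid_norm`` the weighted residual
    norm on the histogram, and ``valid`` whether the fit is accepted
    (converged and w1 maximal).  ``estimate_mcn`` refuses invalid fits.
    """

    q: float
    weights: np.ndarray
    sigma: float
    resid_norm: float
    n_puncta: int
    method: str = "histogram"
    valid: bool = True
    flags: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def summary(self) -> str:
        lines = [
            "Quantal nucleoid intensity fit",
            "=" * 34,
            f"method:        {self.method}",
            f"n puncta:      {self.n_puncta}",
            f"q (a.u.):      {self.q:.4g}",
            f"sigma (a.u.):  {self.sigma:.4g}",
            f"residual norm: {self.resid_norm:.4g}",
            f"valid:         {self.valid}" + (f"  ({'; '.join(self.flags)})"
                                              if self.flags else ""),
            "weights: " + ", ".join(
                f"w{k + 1}={w:.3f}" for k, w in enumerate(self.weights)),
        ]
        return "\n".join(lines)

    def plot(self, intensities=None, ax=None):
        """Histogram of punctum intensities with the fitted mixture overlaid."""
        import matplotlib.pyplot as plt
        from scipy.stats import norm as _norm

        if ax is None:
            _fig, ax = plt.subplots()
        if intensities is not None:
            x = np.asarray(intensities, float)
            ax.hist(x, bins="fd", density=True, alpha=0.4, color="grey",
                    label=f"puncta (n={x.size})")
            grid = np.linspace(0, x.max(), 600)
        else:
            grid = np.linspace(0, self.n_components * self.q * 1.2, 600)
        k = np.arange(1, self.n_components + 1)[:, None]
        pdf = (self.weights[:, None]
               * _norm.pdf(grid[None, :], k * self.q,
                           np.maximum(self.sigma, 1e-9) * np.sqrt(k)))
        ax.plot(grid, pdf.sum(axis=0), "C3", label=f"quantal fit (q={self.q:.3g})")
        for kk in range(min(4, self.n_components)):
            ax.plot(grid, pdf[kk], "C0", lw=0.8, alpha=0.7)
        ax.set_xlabel("integrated punctum intensity (a.u.)")
        ax.set_ylabel("density")
        ax.legend()
        return ax

    def to_frame(self) -> pd.DataFrame:
        row = {"q": self.q, "sigma": self.sigma, "resid_norm": self.resid_norm,
               "n_puncta": self.n_puncta, "method": self.method,
               "valid": self.valid}
        row.update({f"w{k + 1}": w for k, w in enumerate(self.weights)})
        return pd.DataFrame([row])


class QuantalIntensityModel:
    """Constrained Gaussian-mixture model of pooled punctum intensities.

    Parameters
    ----------
    intensities : array-like
        Integrated punctum intensities (a.u.) pooled over one staining batch.
    n_components : int
        Number of copy-number components K (component means k·q, k=1..K).
    min_puncta : int
        Required sample-size floor; fitting fewer puncta raises.
    """

    def __init__(self, intensities, n_components: int = 10,
                 min_puncta: int = 200):
        x = np.asarray(intensities, float)
        x = x[np.isfinite(x) & (x > 0)]
        if x.size < min_puncta:
            raise ValueError(
                f"need >= {min_puncta} puncta to fit the quantal mixture, "
                f"got {x.size}")
        self.intensities = x
        self.n_components = int(n_components)
        self.kvals = np.arange(1, self.n_components + 1)

    # -- histogram machinery --------------------------------------------
    def _histogram(self):
        x = self.intensities
        edges = np.histogram_bin_edges(x, bins="fd")
        if edges.size > 402:  # cap bins for stability on heavy-tailed samples
            edges = np.histogram_bin_edges(x, bins=400)
        counts, edges = np.histogram(x, bins=edges)
        return counts.astype(float), edges

    def _bin_probs(self, edges, q, sigma):
        """P[b, k]: mass of component k inside bin b."""
        k = self.kvals[None, :]
        sk = sigma * np.sqrt(k)
        lo = ndtr((edges[:-1, None] - k * q) / sk)
        hi = ndtr((edges[1:, None] - k * q) / sk)
        return hi - lo

    def _solve_weights(self, counts, edges, q, sigma, bin_w):
        # extend with empty bins out to the top component's upper tail: the
        # observed absence of counts there is what pins down the amplitudes
        # of components beyond the data range
        width = edges[1] - edges[0]
        kmax = self.kvals[-1]
        top = kmax * q + 4.0 * sigma * np.sqrt(kmax)
        if edges[-1] < top:
            n_extra = int(np.ceil((top - edges[-1]) / width))
            edges = np.concatenate(
                [edges, edges[-1] + width * np.arange(1, n_extra + 1)])
            counts = np.concatenate([counts, np.zeros(n_extra)])
            bin_w = np.concatenate([bin_w, np.ones(n_extra)])
        P = self._bin_probs(edges, q, sigma)
        # components with no mass in the histogram range would get arbitrary,
        # numerically huge coefficients; they carry zero weight by definition
        support = P.sum(axis=0) > 1e-6
        A = P[:, support] * bin_w[:, None]
        b = counts * bin_w
        vs, rnorm = optimize.nnls(A, b)
        v = np.zeros(self.n_components)
        v[support] = vs
        total = v.sum()
        w = v / total if total > 0 else np.full(self.n_components, np.nan)
        return w, rnorm, total

    def _fit_histogram(self, n_starts: int) -> QuantalFit:
        x = self.intensities
        counts, edges = self._histogram()
        bin_w = 1.0 / np.sqrt(np.maximum(counts, 1.0))

        if np.ptp(x) == 0:  # degenerate: a single intensity value
            w = np.zeros(self.n_components)
            w[0] = 1.0
            return QuantalFit(q=float(x[0]), weights=w, sigma=0.0,
                              resid_norm=0.0, n_puncta=x.size,
                              method="histogram")

        centers = 0.5 * (edges[:-1] + edges[1:])
        mode = centers[np.argmax(counts)]
        p5 = np.percentile(x, 5)
        lo = max(min(p5, 0.9 * mode), 0.61 * mode, 1e-9)
        hi = max(mode, lo * 1.0001)
        q_starts = np.geomspace(lo, hi, n_starts)

        # identifiability bounds: under the single-copy-dominance assumption
        # q sits near the histogram mode (excludes the q -> q/2 alias, which
        # fits equally well with all odd weights zero), and the single-copy
        # spread must leave the quantal structure resolvable
        bq = (np.log(0.6 * mode), np.log(1.7 * mode))
        bs = (np.log(0.02), np.log(0.35))  # sigma relative to q

        def objective(theta):
            lq = np.clip(theta[0], *bq)
            ls = np.clip(theta[1], *bs)
            q = np.exp(lq)
            sigma = np.exp(ls) * q
            _, rnorm, _ = self._solve_weights(counts, edges, q, sigma, bin_w)
            pen = (theta[0] - lq) ** 2 + (theta[1] - ls) ** 2
            return rnorm * (1.0 + 10.0 * pen)

        best = None
        for q0 in q_starts:
            res = optimize.minimize(
                objective, [np.log(q0), np.log(0.08)], method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 400})
            if best is None or res.fun < best.fun:
                best = res
        q = float(np.exp(np.clip(best.x[0], *bq)))
        sigma = q * float(np.exp(np.clip(best.x[1], *bs)))
        w, rnorm, _ = self._solve_weights(counts, edges, q, sigma, bin_w)

        flags = []
        valid = True
        if not np.all(np.isfinite(w)):
            flags.append("weight solve failed")
            valid = False
            w = np.full(self.n_components, np.nan)
        elif w[0] < w.max() - 1e-9:
            flags.append("first component is not the most abundant")
            valid = False
        return QuantalFit(q=float(q), weights=w, sigma=float(sigma),
                          resid_norm=float(rnorm), n_puncta=x.size,
                          method="histogram", valid=valid, flags=flags)

    # -- EM variant ------------------------------------------------------
    def _fit_em(self, max_iter: int = 500, tol: float = 1e-10) -> QuantalFit:
        x = self.intensities
        if np.ptp(x) == 0:
            w = np.zeros(self.n_components)
            w[0] = 1.0
            return QuantalFit(q=float(x[0]), weights=w, sigma=0.0,
                              resid_norm=0.0, n_puncta=x.size, method="em")
        k = self.kvals[None, :]
        counts, edges = self._histogram()
        centers = 0.5 * (edges[:-1] + edges[1:])
        q = float(centers[np.argmax(counts)])
        sigma = 0.1 * q
        w = np.full(self.n_components, 1.0 / self.n_components)
        ll_old = -np.inf
        for _ in range(max_iter):
            var = np.maximum(sigma * sigma, 1e-12) * k
            logp = (np.log(np.maximum(w[None, :], 1e-300))
                    - 0.5 * np.log(2 * np.pi * var)
                    - 0.5 * (x[:, None] - k * q) ** 2 / var)
            norm = logsumexp(logp, axis=1)
            r = np.exp(logp - norm[:, None])
            ll = norm.sum()
            w = r.mean(axis=0)
            q = float((r * x[:, None]).sum() / (r * k).sum())
            sigma = float(np.sqrt(((r * (x[:, None] - k * q) ** 2 / k).sum())
                                  / x.size))
            if abs(ll - ll_old) < tol * abs(ll):
                break
            ll_old = ll
        flags = []
        valid = bool(w[0] >= w.max() - 1e-9)
        if not valid:
            flags.append("first component is not the most abundant")
        return QuantalFit(q=q, weights=w, sigma=sigma, resid_norm=float(-ll),
                          n_puncta=x.size, method="em", valid=valid,
                          flags=flags)

    def fit(self, method: str = "histogram", n_starts: int = 20) -> QuantalFit:
        """Fit the constrained mixture; see the module docstring for the model."""
        if method == "histogram":
            return self._fit_histogram(n_starts)
        if method == "em":
            return self._fit_em()
        raise ValueError(f"unknown method {method!r}")


def fit_quantal_mixture(intensities, n_components: int = 10,
                        min_puncta: int = 200, **fit_kw) -> QuantalFit:
    """Convenience wrapper: build the model and fit it in one call."""
    return QuantalIntensityModel(
        intensities, n_components=n_components, min_puncta=min_puncta
    ).fit(**fit_kw)


def estimate_mcn(cell_sums, fit: QuantalFit):
    """Per-cell mCN = summed punctum intensity / quantal intensity.

    Real-valued (not rounded); refuses invalid quantal fits because a wrong
    q silently rescales every copy number downstream.
    """
    if not fit.valid:
        raise ValueError(f"quantal fit is invalid: {'; '.join(fit.flags)}")
    if fit.q <= 0:
        raise ValueError("quantal intensity must be > 0")
    sums = pd.Series(cell_sums, dtype=float) if not isinstance(
        cell_sums, pd.Series) else cell_sums.astype(float)
    out = sums / fit.q
    out.name = "mcn"
    return out


def normalize_to_reference(group_values, reference_mean: float):
    """Divide values by a reference-group mean (per plate, per media).

    Normalizing the reference to itself yields 1.0, and the operation is
    idempotent once the reference mean is 1.
    """
    if reference_mean is None or not np.isfinite(reference_mean) or reference_mean <= 0:
        raise ValueError("reference_mean must be a finite positive number")
    vals = np.asarray(group_values, float) if not isinstance(
        group_values, pd.Series) else group_values.astype(float)
    return vals / reference_mean
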