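"""Interval mapping by Haley-Knott regression.

The scan regresses a phenotype on expected additive/dominance dosages
(x_a, x_d) at each evaluation position, with fixed covariates, and
reports LOD = (n/2) * log10(RSS_null / RSS_full).  Genotype
probabilities come from a 3-state forward-backward pass with F2-type
transitions derived from the Haldane map function, so missing genotypes
and between-marker positions are handled.  Genome-wide significance is
assessed by permuting individual labels (trait + covariates jointly
against genotypes); support intervals use the 1.8-LOD-drop rule, which
approximates a 95% confidence interval in intercrosses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cross import CrossData, GeneticMap, GenotypeProbabilities

LOD_DROP_DEFAULT = 1.8
SIGNIFICANT_QUANTILE = 0.95
SUGGESTIVE_QUANTILE = 0.80


def haldane_recomb(d):
    """Haldane map function: r = (1 - exp(-2 d / 100)) / 2 for d in cM."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if r.ndim == 0 else r


def _f2_transition(r: np.ndarray) -> np.ndarray:
    """(m, 3, 3) transition matrices between adjacent positions (F2 prior)."""
    r = np.asarray(r, float)
    s = 1.0 - r
    t = np.empty(r.shape + (3, 3))
    t[..., 0, 0] = s**2; t[..., 0, 1] = 2 * r * s; t[..., 0, 2] = r**2
    t[..., 1, 0] = r * s; t[..., 1, 1] = s**2 + r**2; t[..., 1, 2] = r * s
    t[..., 2, 0] = r**2; t[..., 2, 1] = 2 * r * s; t[..., 2, 2] = s**2
    return t


_F2_PRIOR = np.array([0.25, 0.5, 0.25])


def genotype_probabilities(cross: CrossData, step: float = 0.0,
                           error_prob: float = 0.0) -> GenotypeProbabilities:
    """Posterior genotype probabilities on the marker (+ pseudomarker) grid.

    ``step`` = 0 evaluates at markers only; ``step`` > 0 adds a cM grid.
    ``error_prob`` is the per-marker genotyping error allowance; at 0 a
    typed marker's probabilities are the indicator of the observed call.
    """
    codes = cross.genotype_codes_int()
    chrom_positions, chrom_names, chrom_probs = {}, {}, {}
    col0 = 0
    for chrom in cross.gmap.chromosomes:
        sub = cross.gmap.chrom_table(chrom)
        mpos = sub["cM"].to_numpy(float)
        mnames = list(sub["marker"])
        m = len(mpos)
        obs = codes[:, col0:col0 + m]
        col0 += m
        if m == 0:
            raise ValueError(f"chromosome {chrom} has no markers")
        if step > 0:
            grid = np.arange(mpos[0], mpos[-1] + 1e-9, step)
            pos = np.unique(np.round(np.concatenate([mpos, grid]), 9))
        else:
            pos = mpos
        marker_at = {round(p, 9): i for i, p in enumerate(np.round(mpos, 9))}
        names, obs_idx = [], []
        for p in pos:
            j = marker_at.get(round(p, 9))
            names.append(mnames[j] if j is not None else f"c{chrom}.loc{p:g}")
            obs_idx.append(j if j is not None else -1)
        obs_idx = np.array(obs_idx)
        n_ind, n_pos = codes.shape[0], len(pos)

        # emission likelihoods (n_pos, n_ind, 3)
        emit = np.ones((n_pos, n_ind, 3))
        for k, j in enumerate(obs_idx):
            if j < 0:
                continue
            o = obs[:, j]
            typed = o >= 0
            e = np.full((n_ind, 3), 1.0)
            e[typed] = error_prob / 2.0
            e[typed, o[typed]] = 1.0 - error_prob
            emit[k] = e
        trans = _f2_transition(haldane_recomb(np.diff(pos)))

        alpha = np.empty((n_pos, n_ind, 3))
        a = _F2_PRIOR[None, :] * emit[0]
        norm = a.sum(axis=1, keepdims=True)
        alpha[0] = a / norm
        for k in range(1, n_pos):
            a = (alpha[k - 1] @ trans[k - 1]) * emit[k]
            a /= a.sum(axis=1, keepdims=True)
            alpha[k] = a
        beta = np.empty((n_pos, n_ind, 3))
        beta[-1] = 1.0
        for k in range(n_pos - 2, -1, -1):
            b = (beta[k + 1] * emit[k + 1]) @ trans[k].T
            b /= b.sum(axis=1, keepdims=True)
            beta[k] = b
        post = alpha * beta
        post /= post.sum(axis=2, keepdims=True)
        chrom_positions[chrom] = pos
        chrom_names[chrom] = names
        chrom_probs[chrom] = post
    return GenotypeProbabilities(chrom_positions, chrom_names, chrom_probs)


# ---------------------------------------------------------------------------
# Design handling


def _encode_covariates(cov: pd.DataFrame, columns) -> tuple[np.ndarray, list]:
    """Numeric columns as-is, categorical/object columns as dummies."""
    mats, names = [], []
    for col in columns:
        if col not in cov.columns:
            raise KeyError(f"covariate {col!r} not found")
        s = cov[col]
        if isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object or s.dtype == bool:
            d = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            mats.append(d.to_numpy())
            names.extend(d.columns)
        else:
            mats.append(s.to_numpy(float)[:, None])
            names.append(col)
    if mats:
        return np.hstack(mats), names
    return np.empty((len(cov), 0)), []


def _check_full_rank(x: np.ndarray, names: list) -> None:
    rank = 0
    for j in range(x.shape[1]):
        r = np.linalg.matrix_rank(x[:, : j + 1])
        if r == rank:
            raise ValueError(f"collinear covariate design: column {names[j]!r} is redundant")
        rank = r


@dataclass
class ScanResult:
    """Per-position LOD curve with the fitted model's descriptor."""

    table: pd.DataFrame  # chrom, name, cM, lod
    trait: str
    covariates: tuple
    interactive_covariate: str | None
    n: int

    def max_lod(self) -> float:
        return float(self.table["lod"].max())

    def peak(self) -> pd.Series:
        return self.table.loc[self.table["lod"].idxmax()]

    def chrom(self, chrom) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]


def _prepare(cross: CrossData, trait: str, additive_covariates,
             interactive_covariate, probs: GenotypeProbabilities | None,
             step: float, error_prob: float):
    if probs is None:
        probs = genotype_probabilities(cross, step=step, error_prob=error_prob)
    y_all = cross.phenotypes[trait].to_numpy(float)
    cov_cols = list(additive_covariates)
    ic = interactive_covariate
    cov_df = cross.covariates
    need = cov_cols + ([ic] if ic and ic not in cov_cols else [])
    keep = ~np.isnan(y_all)
    for col in need:
        if col not in cov_df.columns:
            raise KeyError(f"covariate {col!r} not found")
        keep &= cov_df[col].notna().to_numpy()
    y = y_all[keep]
    if len(y) < 3:
        raise ValueError("fewer than 3 complete observations")
    if np.var(y) == 0:
        raise ValueError(f"trait {trait!r} has zero variance")
    cmat, cnames = _encode_covariates(cov_df.loc[keep], cov_cols)
    if ic is not None:
        icmat, icnames = _encode_covariates(cov_df.loc[keep], [ic])
        extra = [nm for nm in icnames if nm not in cnames]
        if extra or ic not in cov_cols:
            sel = [icnames.index(nm) for nm in icnames if nm not in cnames]
            if sel:
                cmat = np.hstack([cmat, icmat[:, sel]])
                cnames = cnames + [icnames[i] for i in sel]
        icmat = icmat
    else:
        icmat = None
    C = np.hstack([np.ones((len(y), 1)), cmat])
    _check_full_rank(C, ["intercept"] + cnames)
    return probs, y, C, ["intercept"] + cnames, icmat, keep


def _genotype_block(D: np.ndarray, icmat: np.ndarray | None) -> np.ndarray:
    """(npos, n, k) genotype design: (x_a, x_d) plus interactions."""
    if icmat is None:
        return D
    inter = D[:, :, :, None] * icmat[None, :, None, :]
    inter = inter.reshape(D.shape[0], D.shape[1], -1)
    return np.concatenate([D, inter], axis=2)


def _lod_curves(G: np.ndarray, perms: np.ndarray, Q0: np.ndarray,
                ystar: np.ndarray, rss0: float, n: int) -> np.ndarray:
    """LOD for each position and each permutation of the genotype rows.

    ``G``: (npos, n, k) genotype design, ``perms``: (c, n) row indices.
    Uses Frisch-Waugh: residualize G on the covariate basis Q0, then the
    explained sum of squares is v' (B'B)^+ v with v = B' y*.
    """
    Gp = G[:, perms, :]                                   # (npos, c, n, k)
    B = Gp - Q0 @ (Q0.T @ Gp)
    Bt = np.swapaxes(B, -1, -2)
    Gram = Bt @ B                                          # (npos, c, k, k)
    v = Bt @ ystar
    k = Gram.shape[-1]
    # tiny ridge keeps degenerate dosage columns (whose v-component is also
    # ~0) from blowing up the batched solve
    trace = Gram.reshape(*Gram.shape[:-2], k * k)[..., :: k + 1].sum(-1)
    ridge = 1e-12 * trace[..., None, None] + 1e-300
    sol = np.linalg.solve(Gram + ridge * np.eye(k), v[..., None])[..., 0]
    explained = np.sum(v * sol, axis=-1)
    rss1 = np.clip(rss0 - explained, 1e-300, None)
    return np.clip((n / 2.0) * np.log10(rss0 / rss1), 0.0, None)


def scanone_hk(cross: CrossData, trait: str, additive_covariates=(),
               interactive_covariate: str | None = None,
               probs: GenotypeProbabilities | None = None,
               step: float = 0.0, error_prob: float = 0.0) -> ScanResult:
    """Genome scan: LOD at every evaluation position.

    The null model regresses the trait on intercept + additive covariates
    (+ the interactive covariate's main effect); the full model adds x_a,
    x_d and, when an interactive covariate is given, their interactions
    with it.  Individuals with missing trait or covariates are dropped.
    """
    probs, y, C, _, icmat, keep = _prepare(
        cross, trait, additive_covariates, interactive_covariate, probs, step, error_prob)
    n = len(y)
    Q0, _ = np.linalg.qr(C)
    ystar = y - Q0 @ (Q0.T @ y)
    rss0 = float(ystar @ ystar)
    ident = np.arange(n)[None, :]
    rows = []
    for chrom in probs.chromosomes:
        D = probs.dosages(chrom)[:, keep, :]
        G = _genotype_block(D, icmat)
        lod = _lod_curves(G, ident, Q0, ystar, rss0, n)[:, 0]
        for nm, cm, l in zip(probs.chrom_names[chrom], probs.chrom_positions[chrom], lod):
            rows.append((chrom, nm, float(cm), float(l)))
    table = pd.DataFrame(rows, columns=["chrom", "name", "cM", "lod"])
    return ScanResult(table=table, trait=trait,
                      covariates=tuple(additive_covariates),
                      interactive_covariate=interactive_covariate, n=n)


@dataclass
class PermutationResult:
    """Genome-wide max-LOD null distribution from label shuffling."""

    maxima: np.ndarray
    quantiles: dict

    def threshold(self, q: float) -> float:
        if not 0 < q < 1:
            raise ValueError("quantile must be in (0, 1)")
        if q not in self.quantiles:
            self.quantiles[q] = float(np.quantile(self.maxima, q))
        return self.quantiles[q]

    def pvalue(self, observed: float) -> float:
        """Genome-wide p: fraction of permuted maxima >= observed."""
        return float(np.mean(self.maxima >= observed))


def permutation_thresholds(cross: CrossData, trait: str, additive_covariates=(),
                           interactive_covariate: str | None = None,
                           n_perm: int = 1000, quantiles=(SIGNIFICANT_QUANTILE, SUGGESTIVE_QUANTILE),
                           seed: int | None = None,
                           rng: np.random.Generator | None = None,
                           probs: GenotypeProbabilities | None = None,
                           step: float = 0.0, error_prob: float = 0.0,
                           chunk: int = 50) -> PermutationResult:
    """Null distribution of the genome-wide maximum LOD.

    Individual labels are shuffled: trait and covariate rows move
    together against the genotype rows, preserving trait-covariate
    association under the no-QTL null.  Implemented by permuting the
    genotype rows, which yields the identical LOD.
    """
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    for q in quantiles:
        if not 0 < q < 1:
            raise ValueError("quantiles must be in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    probs, y, C, _, icmat, keep = _prepare(
        cross, trait, additive_covariates, interactive_covariate, probs, step, error_prob)
    n = len(y)
    Q0, _ = np.linalg.qr(C)
    ystar = y - Q0 @ (Q0.T @ y)
    rss0 = float(ystar @ ystar)
    blocks = []
    for ch in probs.chromosomes:
        G = _genotype_block(probs.dosages(ch)[:, keep, :], icmat)
        npos, _, k = G.shape
        Gt2 = np.ascontiguousarray(G.transpose(0, 2, 1)).reshape(npos * k, n)
        GtG = np.swapaxes(G, 1, 2) @ G
        blocks.append((Gt2, GtG, npos, k))
    maxima = np.empty(n_perm)
    done = 0
    while done < n_perm:
        c = min(chunk, n_perm - done)
        perms = np.stack([rng.permutation(n) for _ in range(c)])
        # permuting genotype rows == applying the same relabeling to the
        # covariate basis and residualized trait; G'G is label-invariant
        Qs = np.ascontiguousarray(Q0[perms].transpose(1, 0, 2)).reshape(n, -1)
        Ys = ystar[perms].T                                   # (n, c)
        q = Q0.shape[1]
        best = np.zeros(c)
        for Gt2, GtG, npos, k in blocks:
            T = (Gt2 @ Qs).reshape(npos, k, c, q)
            V = (Gt2 @ Ys).reshape(npos, k, c)
            Tt = T.transpose(0, 2, 1, 3)                      # (npos, c, k, q)
            Gram = GtG[:, None] - Tt @ np.swapaxes(Tt, -1, -2)
            v = np.moveaxis(V, -1, 1)                         # (npos, c, k)
            trace = Gram.reshape(npos, c, k * k)[..., :: k + 1].sum(-1)
            ridge = 1e-12 * trace[..., None, None] + 1e-300
            sol = np.linalg.solve(Gram + ridge * np.eye(k), v[..., None])[..., 0]
            explained = np.sum(v * sol, axis=-1)
            rss1 = np.clip(rss0 - explained, 1e-300, None)
            lod = np.clip((n / 2.0) * np.log10(rss0 / rss1), 0.0, None)
            best = np.maximum(best, lod.max(axis=0))
        maxima[done:done + c] = best
        done += c
    return PermutationResult(maxima=maxima,
                             quantiles={q: float(np.quantile(maxima, q)) for q in quantiles})


# ---------------------------------------------------------------------------
# Peaks


@dataclass
class QTLPeak:
    """One mapped locus, mirroring the standard peaks-table columns."""

    trait: str
    marker: str
    chrom: str
    position: float
    lod: float
    pvalue: float | None
    ci_start: float
    ci_end: float
    additive_effect: float
    additive_se: float
    dominance_effect: float
    dominance_se: float
    pct_var: float
    tier: str | None = None

    def as_row(self) -> dict:
        return {
            "trait": self.trait, "marker": self.marker, "chrom": self.chrom,
            "pos": self.position, "lod": self.lod, "pvalue": self.pvalue,
            "ci_start": self.ci_start, "ci_end": self.ci_end,
            "add_effect": self.additive_effect, "add_se": self.additive_se,
            "dom_effect": self.dominance_effect, "dom_se": self.dominance_se,
            "pct_var": self.pct_var, "tier": self.tier,
        }


def lod_drop_interval(scan: ScanResult, chrom, peak_pos: float,
                      drop: float = LOD_DROP_DEFAULT,
                      gmap: GeneticMap | None = None) -> tuple[float, float]:
    """Support interval: outermost positions with LOD >= peak - drop.

    Walks outward from the peak until the LOD falls below peak - drop (or
    the chromosome end) and snaps the endpoints to the closest markers
    when a map is given.  The 1.8-LOD default approximates a 95% CI.
    """
    sub = scan.chrom(chrom).reset_index(drop=True)
    if sub.empty:
        raise ValueError(f"no scan positions on chromosome {chrom!r}")
    pos = sub["cM"].to_numpy(float)
    lod = sub["lod"].to_numpy(float)
    hits = np.nonzero(np.isclose(pos, peak_pos, atol=1e-9))[0]
    if len(hits) == 0:
        raise ValueError(f"peak position {peak_pos} is not on the scan grid")
    k = int(hits[0])
    cut = lod[k] - drop
    lo = k
    while lo > 0 and lod[lo - 1] >= cut:
        lo -= 1
    hi = k
    while hi < len(lod) - 1 and lod[hi + 1] >= cut:
        hi += 1
    ci_lo, ci_hi = float(pos[lo]), float(pos[hi])
    if gmap is not None:
        ci_lo = float(gmap.nearest_marker(chrom, ci_lo)["cM"])
        ci_hi = float(gmap.nearest_marker(chrom, ci_hi)["cM"])
    return ci_lo, ci_hi


def qtl_fit(cross: CrossData, trait: str, additive_covariates=(),
            chrom=None, position: float = None,
            probs: GenotypeProbabilities | None = None,
            interactive_covariate: str | None = None,
            error_prob: float = 0.0) -> QTLPeak:
    """Effect estimates at a peak: a, d with SEs, and partial R^2 (%Var).

    Fits the same full model as the scan at one position by ordinary
    least squares; %Var is the partial R^2 of (x_a, x_d) given the
    covariates, times 100.
    """
    import statsmodels.api as sm

    probs, y, C, cnames, icmat, keep = _prepare(
        cross, trait, additive_covariates, interactive_covariate, probs, 0.0, error_prob)
    pos_arr = probs.chrom_positions[chrom]
    hits = np.nonzero(np.isclose(pos_arr, position, atol=1e-9))[0]
    if len(hits) == 0:
        raise ValueError(f"position {position} not on the evaluation grid of {chrom!r}")
    k = int(hits[0])
    D = probs.dosages(chrom)[k][keep]          # (n, 2)
    G = _genotype_block(D[None], icmat)[0]
    X = np.hstack([C, G])
    fit = sm.OLS(y, X).fit()
    j = C.shape[1]
    rss1 = float(fit.ssr)
    Q0, _ = np.linalg.qr(C)
    ystar = y - Q0 @ (Q0.T @ y)
    rss0 = float(ystar @ ystar)
    pct = 100.0 * max(rss0 - rss1, 0.0) / rss0 if rss0 > 0 else 0.0
    name = probs.chrom_names[chrom][k]
    return QTLPeak(
        trait=trait, marker=name, chrom=str(chrom), position=float(pos_arr[k]),
        lod=float((len(y) / 2.0) * np.log10(max(rss0, 1e-300) / max(rss1, 1e-300))),
        pvalue=None, ci_start=np.nan, ci_end=np.nan,
        additive_effect=float(fit.params[j]), additive_se=float(fit.bse[j]),
        dominance_effect=float(fit.params[j + 1]), dominance_se=float(fit.bse[j + 1]),
        pct_var=float(pct),
    )


def find_qtl_peaks(cross: CrossData, trait: str, additive_covariates=(),
                   interactive_covariate: str | None = None,
                   n_perm: int = 1000, seed: int | None = None,
                   rng: np.random.Generator | None = None,
                   probs: GenotypeProbabilities | None = None,
                   drop: float = LOD_DROP_DEFAULT) -> list:
    """Scan + permutations + per-chromosome peaks above the 0.80 quantile.

    Peaks at or above the 0.95 quantile are tiered "significant", those
    between 0.80 and 0.95 "suggestive"; each carries its genome-wide
    p-value, 1.8-LOD-drop CI (marker-snapped) and effect estimates.
    """
    if probs is None:
        probs = genotype_probabilities(cross)
    scan = scanone_hk(cross, trait, additive_covariates, interactive_covariate, probs=probs)
    perm = permutation_thresholds(cross, trait, additive_covariates,
                                  interactive_covariate, n_perm=n_perm,
                                  seed=seed, rng=rng, probs=probs)
    sug = perm.threshold(SUGGESTIVE_QUANTILE)
    sig = perm.threshold(SIGNIFICANT_QUANTILE)
    peaks = []
    for chrom in probs.chromosomes:
        sub = scan.chrom(chrom)
        best = sub.loc[sub["lod"].idxmax()]
        if best["lod"] < sug:
            continue
        ci = lod_drop_interval(scan, chrom, best["cM"], drop=drop, gmap=cross.gmap)
        peak = qtl_fit(cross, trait, additive_covariates, chrom, best["cM"],
                       probs=probs, interactive_covariate=interactive_covariate)
        peak.pvalue = perm.pvalue(float(best["lod"]))
        peak.ci_start, peak.ci_end = ci
        peak.tier = "significant" if best["lod"] >= sig else "suggestive"
        peaks.append(peak)
    return peaks
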