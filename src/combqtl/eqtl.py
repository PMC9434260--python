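"""Expression QTL mapping and cis/trans classification.

Each probe's expression is scanned genome-wide like any quantitative
trait (batch as the fixed covariate by default).  A probe whose maximum
LOD clears the suggestive (0.80-quantile) permutation threshold yields
one record — its genome-wide best peak — classified *cis* (local) if the
probe lies within 50 cM of the peak marker on the same chromosome, and
*trans* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cross import CrossData, GenotypeProbabilities
from .qtl import (SIGNIFICANT_QUANTILE, SUGGESTIVE_QUANTILE, LOD_DROP_DEFAULT,
                  _encode_covariates, _check_full_rank, _genotype_block,
                  genotype_probabilities, lod_drop_interval, ScanResult)

CIS_WINDOW_DEFAULT = 50.0  # cM


@dataclass
class EQTLRecord:
    """Best genome-wide peak of one expression trait."""

    probe: str
    marker: str
    chrom: str
    position: float
    lod: float
    pvalue: float
    ci_start: float
    ci_end: float
    tier: str
    klass: str | None = None  # "cis" | "trans" | None when unplaced

    def as_row(self) -> dict:
        return {
            "probe": self.probe, "class": self.klass, "marker": self.marker,
            "chrom": self.chrom, "pos": self.position, "lod": self.lod,
            "pvalue": self.pvalue, "ci_start": self.ci_start,
            "ci_end": self.ci_end, "tier": self.tier,
        }


def classify_cis_trans(peak_chrom, peak_cm: float, probe_chrom, probe_cm,
                       window: float = CIS_WINDOW_DEFAULT) -> str | None:
    """Cis iff same chromosome and |probe - peak| <= window (inclusive).

    Returns ``None`` (unclassifiable) for unplaced probes.
    """
    if probe_chrom is None or (isinstance(probe_cm, float) and np.isnan(probe_cm)):
        return None
    if str(probe_chrom) != str(peak_chrom):
        return "trans"
    return "cis" if abs(float(probe_cm) - float(peak_cm)) <= window else "trans"


def _multi_lod(Ystar: np.ndarray, rss0: np.ndarray, Qb: np.ndarray, n: int) -> np.ndarray:
    """(npos, nprobe) LOD from an orthonormal genotype basis Qb (npos,n,k)."""
    proj = np.einsum("pnk,nt->pkt", Qb, Ystar)
    explained = np.einsum("pkt,pkt->pt", proj, proj)
    rss1 = np.clip(rss0[None, :] - explained, 1e-300, None)
    return np.clip((n / 2.0) * np.log10(rss0[None, :] / rss1), 0.0, None)


def _orthobasis(G: np.ndarray, Q0: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the covariate-residualized genotype design."""
    B = G - np.einsum("nq,pqk->pnk", Q0, np.einsum("nq,pnk->pqk", Q0, G))
    Qb, R = np.linalg.qr(B)
    # zero out directions with negligible column norm (collinear dosages)
    diag = np.abs(np.einsum("pkk->pk", R))
    Qb = Qb * (diag > 1e-9 * max(np.abs(B).max(), 1.0))[:, None, :]
    return Qb


def scan_expression(cross: CrossData, expression: pd.DataFrame,
                    additive_covariates=("batch",),
                    annotation: pd.DataFrame | None = None,
                    window: float = CIS_WINDOW_DEFAULT,
                    n_perm: int = 1000,
                    quantiles=(SIGNIFICANT_QUANTILE, SUGGESTIVE_QUANTILE),
                    seed: int | None = None,
                    rng: np.random.Generator | None = None,
                    probs: GenotypeProbabilities | None = None,
                    drop: float = LOD_DROP_DEFAULT,
                    perm_chunk: int = 25) -> list:
    """Map every probe and keep those passing the suggestive threshold.

    ``expression``: probes x individuals with columns matching the cross
    individuals.  ``annotation``: probe, chrom, cM (optional; needed for
    cis/trans labels).  Permutations shuffle individual labels jointly
    for expression and covariates against genotypes; the same label
    shuffles are shared across probes, giving each probe its own
    genome-wide max-LOD null.
    """
    if expression.empty:
        raise ValueError("expression matrix is empty")
    ids = list(cross.individual_ids)
    missing = [i for i in ids if i not in expression.columns]
    extra = [c for c in expression.columns if c not in ids]
    if missing or extra:
        raise ValueError(
            f"individual ids mismatch: missing from expression {missing[:5]}, "
            f"not in cross {extra[:5]}")
    Y = expression[ids].to_numpy(float).T  # (n, nprobe)
    if np.isnan(Y).any():
        bad = expression.index[np.isnan(Y).any(axis=0)]
        raise ValueError(f"expression has missing values for probes {list(bad[:5])}")
    if probs is None:
        probs = genotype_probabilities(cross)
    if rng is None:
        rng = np.random.default_rng(seed)
    n, n_probe = Y.shape
    cmat, cnames = _encode_covariates(cross.covariates, list(additive_covariates))
    C = np.hstack([np.ones((n, 1)), cmat])
    _check_full_rank(C, ["intercept"] + cnames)
    Q0, _ = np.linalg.qr(C)
    Ystar = Y - Q0 @ (Q0.T @ Y)
    rss0 = np.einsum("nt,nt->t", Ystar, Ystar)
    if np.any(rss0 <= 0):
        bad = expression.index[rss0 <= 0]
        raise ValueError(f"zero-variance expression for probes {list(bad[:5])}")

    blocks = {ch: _genotype_block(probs.dosages(ch), None) for ch in probs.chromosomes}
    lod_rows, meta = [], []
    for ch in probs.chromosomes:
        lod = _multi_lod(Ystar, rss0, _orthobasis(blocks[ch], Q0), n)
        lod_rows.append(lod)
        meta.extend((ch, nm, cm) for nm, cm in
                    zip(probs.chrom_names[ch], probs.chrom_positions[ch]))
    LOD = np.vstack(lod_rows)  # (npos_total, nprobe)

    pre = {}
    for ch in probs.chromosomes:
        G = blocks[ch]
        npos, _, k = G.shape
        Gt2 = np.ascontiguousarray(G.transpose(0, 2, 1)).reshape(npos * k, n)
        pre[ch] = (Gt2, np.swapaxes(G, 1, 2) @ G, npos, k)
    q = Q0.shape[1]
    maxima = np.empty((n_perm, n_probe))
    done = 0
    while done < n_perm:
        c = min(perm_chunk, n_perm - done)
        perms = np.stack([rng.permutation(n) for _ in range(c)])
        # relabel the covariate basis and residualized expression jointly:
        # equivalent to permuting genotype rows, and G'G is label-invariant
        Qs = np.ascontiguousarray(Q0[perms].transpose(1, 0, 2)).reshape(n, c * q)
        Ys = np.ascontiguousarray(Ystar[perms].transpose(1, 0, 2)).reshape(n, c * n_probe)
        best = np.zeros((c, n_probe))
        for ch in probs.chromosomes:
            Gt2, GtG, npos, k = pre[ch]
            T = (Gt2 @ Qs).reshape(npos, k, c, q).transpose(0, 2, 1, 3)
            V = (Gt2 @ Ys).reshape(npos, k, c, n_probe).transpose(0, 2, 1, 3)
            Gram = GtG[:, None] - T @ np.swapaxes(T, -1, -2)
            trace = Gram.reshape(npos, c, k * k)[..., :: k + 1].sum(-1)
            ridge = 1e-12 * trace[..., None, None] + 1e-300
            sol = np.linalg.solve(Gram + ridge * np.eye(k), V)
            explained = np.sum(V * sol, axis=2)                  # (npos, c, t)
            rss1 = np.clip(rss0[None, None, :] - explained, 1e-300, None)
            lod = np.clip((n / 2.0) * np.log10(rss0[None, None, :] / rss1), 0.0, None)
            best = np.maximum(best, lod.max(axis=0))
        maxima[done:done + c] = best
        done += c

    sig_thr = np.quantile(maxima, SIGNIFICANT_QUANTILE, axis=0)
    sug_thr = np.quantile(maxima, SUGGESTIVE_QUANTILE, axis=0)
    annot_by_probe = {}
    if annotation is not None:
        for _, row in annotation.iterrows():
            annot_by_probe[row["probe"]] = (row.get("chrom"), row.get("cM"))

    records = []
    probe_ids = list(expression.index)
    for t, probe in enumerate(probe_ids):
        best_idx = int(np.argmax(LOD[:, t]))
        best_lod = float(LOD[best_idx, t])
        if best_lod < sug_thr[t]:
            continue
        ch, name, cm = meta[best_idx]
        scan = ScanResult(
            table=pd.DataFrame({
                "chrom": [m[0] for m in meta], "name": [m[1] for m in meta],
                "cM": [m[2] for m in meta], "lod": LOD[:, t]}),
            trait=str(probe), covariates=tuple(additive_covariates),
            interactive_covariate=None, n=n)
        ci_lo, ci_hi = lod_drop_interval(scan, ch, cm, drop=drop, gmap=cross.gmap)
        pchrom, pcm = annot_by_probe.get(probe, (None, np.nan))
        records.append(EQTLRecord(
            probe=str(probe), marker=name, chrom=str(ch), position=float(cm),
            lod=best_lod, pvalue=float(np.mean(maxima[:, t] >= best_lod)),
            ci_start=ci_lo, ci_end=ci_hi,
            tier="significant" if best_lod >= sig_thr[t] else "suggestive",
            klass=classify_cis_trans(ch, cm, pchrom, pcm, window=window),
        ))
    return records


def eqtl_table(records) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in records])
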