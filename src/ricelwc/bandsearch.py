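"""Exhaustive two-band normalised-difference screening against leaf water
content.

For every unordered wavelength pair (l1, l2) on the grid, ND(l1, l2) is
regressed against LWC by simple ordinary least squares and the R^2 and
RMSE of the fit are stored as band-by-band matrices.  For a simple linear
regression R^2 equals the squared Pearson correlation between ND and LWC
and the fitted RMSE is sd(LWC)*sqrt(1 - R^2), which allows the whole scan
to be vectorised over band pairs; only the upper triangle is computed and
the lower triangle mirrored (the fit is exactly invariant under swapping
the pair, which negates ND).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .records import SpectraCollection, ValidationError


@dataclass
class BandSearchResult:
    """R^2/RMSE surfaces over all band pairs for one growth stage.

    Matrices are indexed by ``wavelengths`` on both axes; undefined cells
    (the diagonal, and pairs whose ND is constant across samples) are NaN.
    """

    stage: str
    wavelengths: np.ndarray
    r2_matrix: np.ndarray
    rmse_matrix: np.ndarray
    best_pair: tuple[int, int]
    best_r2: float
    best_rmse: float
    n_samples: int


def scan_pairs(coll: SpectraCollection, lwc: np.ndarray, stage: str = "",
               step: int = 1) -> BandSearchResult:
    """Scan all band pairs of ``coll`` (optionally decimated by ``step``)
    against ``lwc`` and select the pair maximising R^2.

    Ties are broken by smaller RMSE, then by the lexicographically smaller
    (l1, l2); the row-major upper-triangle argmax implements this since
    RMSE is a monotone transform of R^2 within one scan.
    """
    y = np.asarray(lwc, dtype=float)
    if len(coll) != y.size:
        raise ValidationError("spectra and LWC are not keyed identically")
    if y.size < 3:
        raise ValidationError(f"need >= 3 samples, got {y.size}")
    wl = coll.wavelengths[::step]
    R = coll.reflectance[:, ::step]
    n, B = R.shape

    y_mean = y.mean()
    var_y = np.mean((y - y_mean) ** 2)
    if var_y == 0:
        raise ValidationError("LWC is constant; R^2 undefined")

    r2 = np.full((B, B), np.nan)
    rmse = np.full((B, B), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(B - 1):
            rest = R[:, i + 1:]
            a = R[:, i][:, None]
            nd = (a - rest) / (a + rest)
            nd_mean = nd.mean(axis=0)
            cov = nd.T @ y / n - nd_mean * y_mean
            var_nd = np.einsum("ij,ij->j", nd, nd) / n - nd_mean ** 2
            cell_r2 = cov ** 2 / (var_nd * var_y)
            cell_r2[var_nd <= 0] = np.nan
            cell_r2 = np.clip(cell_r2, 0.0, 1.0)
            r2[i, i + 1:] = cell_r2
            rmse[i, i + 1:] = np.sqrt(var_y * (1.0 - cell_r2))
    # mirror: the fit is swap-symmetric
    iu = np.triu_indices(B, k=1)
    r2[(iu[1], iu[0])] = r2[iu]
    rmse[(iu[1], iu[0])] = rmse[iu]

    upper_r2 = np.where(np.triu(np.ones((B, B), dtype=bool), k=1), r2, np.nan)
    if np.all(np.isnan(upper_r2)):
        raise ValidationError("every band pair is degenerate")
    flat = np.nanargmax(upper_r2)
    bi, bj = np.unravel_index(flat, upper_r2.shape)
    return BandSearchResult(
        stage=stage, wavelengths=wl, r2_matrix=r2, rmse_matrix=rmse,
        best_pair=(int(wl[bi]), int(wl[bj])), best_r2=float(r2[bi, bj]),
        best_rmse=float(rmse[bi, bj]), n_samples=n)


def scan_pairs_bruteforce(coll: SpectraCollection, lwc: np.ndarray,
                          stage: str = "", step: int = 1) -> BandSearchResult:
    """Naive double-loop reference scan (per-pair ``np.polyfit``).

    Slow; intended for cross-checking the vectorised scan on small grids.
    """
    y = np.asarray(lwc, dtype=float)
    wl = coll.wavelengths[::step]
    R = coll.reflectance[:, ::step]
    B = wl.size
    r2 = np.full((B, B), np.nan)
    rmse = np.full((B, B), np.nan)
    for i in range(B):
        for j in range(B):
            if i == j:
                continue
            nd = (R[:, i] - R[:, j]) / (R[:, i] + R[:, j])
            if np.ptp(nd) == 0:
                continue
            slope, intercept = np.polyfit(nd, y, 1)
            pred = slope * nd + intercept
            ss_res = np.sum((y - pred) ** 2)
            ss_tot = np.sum((y - y.mean()) ** 2)
            r2[i, j] = 1.0 - ss_res / ss_tot
            rmse[i, j] = np.sqrt(ss_res / y.size)
    upper = np.where(np.triu(np.ones((B, B), dtype=bool), k=1), r2, np.nan)
    bi, bj = np.unravel_index(np.nanargmax(upper), upper.shape)
    return BandSearchResult(stage=stage, wavelengths=wl, r2_matrix=r2,
                            rmse_matrix=rmse,
                            best_pair=(int(wl[bi]), int(wl[bj])),
                            best_r2=float(r2[bi, bj]), best_rmse=float(rmse[bi, bj]),
                            n_samples=y.size)


def _significance_marker(p: float) -> str:
    return "**" if p < 0.01 else ("*" if p < 0.05 else "")


def stage_table(results: dict[str, BandSearchResult],
                index_tables: dict[str, pd.DataFrame],
                lwc_column: str = "LWC") -> pd.DataFrame:
    """Per-stage R^2 of LWC against the best-pair ND and the five classical
    indices, with 5%/1% significance markers from the regression F test.

    ``index_tables`` maps stage -> a frame with ND/NDVI/NDII/NDWI/WI/MSI and
    LWC columns for the same samples used in the scan.
    """
    rows = []
    for stage, res in results.items():
        tab = index_tables[stage]
        y = tab[lwc_column].to_numpy(float)
        row: dict[str, object] = {"stage": stage,
                                  "ND_pair": f"({res.best_pair[0]},{res.best_pair[1]})"}
        for col in ["ND", "NDVI", "NDII", "NDWI", "WI", "MSI"]:
            x = tab[col].to_numpy(float)
            r, p = stats.pearsonr(x, y)
            row[col] = r ** 2
            row[f"{col}_sig"] = _significance_marker(p)
        rows.append(row)
    return pd.DataFrame(rows)


def export_heatmap(result: BandSearchResult, out_dir, prefix: str = "") -> dict:
    """Write R^2/RMSE matrices as TSV plus rendered heat maps (PNG).

    Masked (NaN) cells are left blank in the TSV and shown in a distinct
    colour in the image; the selected optimum is marked.  Returns the paths
    written.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    wl = result.wavelengths
    for name, mat in [("r2", result.r2_matrix), ("rmse", result.rmse_matrix)]:
        tsv = out_dir / f"{prefix}{name}_matrix.tsv"
        pd.DataFrame(mat, index=wl, columns=wl).to_csv(tsv, sep="\t")
        paths[f"{name}_tsv"] = tsv

        fig, ax = plt.subplots(figsize=(6, 5))
        cmap = plt.get_cmap("viridis").copy()
        cmap.set_bad("lightgrey")
        im = ax.imshow(np.ma.masked_invalid(mat), origin="lower", cmap=cmap,
                       extent=[wl[0], wl[-1], wl[0], wl[-1]], aspect="auto")
        ax.plot(result.best_pair[1], result.best_pair[0], "r+", ms=12, mew=2)
        ax.set_xlabel("wavelength $\\lambda_2$ (nm)")
        ax.set_ylabel("wavelength $\\lambda_1$ (nm)")
        ax.set_title(f"{result.stage} {name.upper()}")
        fig.colorbar(im, ax=ax)
        png = out_dir / f"{prefix}{name}_heatmap.png"
        fig.savefig(png, dpi=120)
        plt.close(fig)
        paths[f"{name}_png"] = png
    return paths
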