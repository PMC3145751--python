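"""Topology tests on per-site log-likelihoods: RELL, weighted KH/SH, AU.

Candidate topologies are compared without re-optimizing anything: the only
input is the candidates x sites matrix of per-site log-likelihoods.  The
RELL bootstrap ("resampling estimated log-likelihoods") draws columns with
replacement — one shared draw across candidates per replicate, so the
replicate log-likelihood differences keep their correlations — and the test
battery derives:

* ``p_wkh`` — weighted Kishino-Hasegawa: one-sided test of candidate i
  against the maximum-likelihood candidate, the observed statistic being
  the replicate-sd-standardized log-likelihood difference and the null its
  centered RELL distribution.
* ``p_wsh`` — weighted Shimodaira-Hasegawa: same observed statistic, but
  the null replicates take the maximum of the standardized differences over
  all candidates (the multiplicity correction); with the shared replicate
  stream this makes p_wsh >= p_wkh cell by cell.
* ``p_au`` — approximately unbiased test: bootstrap probabilities of being
  best at several resampling scales r, a weighted least-squares fit of
  z(r) = d sqrt(r) + c / sqrt(r) to the probit-transformed probabilities,
  and p_au = 1 - Phi(d - c).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._rng import rng_for
from .io import Alignment
from .likelihood import site_likelihoods
from .models import SubstModel

__all__ = [
    "SiteLnLMatrix",
    "TopologyTestResult",
    "site_lnl_matrix",
    "rell_resample",
    "kh_sh_tests",
    "au_test",
    "run_topology_tests",
    "test_report",
    "DEFAULT_AU_SCALES",
]

DEFAULT_AU_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 2))


@dataclass
class SiteLnLMatrix:
    """Candidates x columns per-site log-likelihoods."""

    names: list[str]
    matrix: np.ndarray  # (n_candidates, n_sites)
    alignment_checksum: str = ""

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or len(self.names) != self.matrix.shape[0]:
            raise ValueError("matrix shape does not match candidate names")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite per-site log-likelihoods")

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    @property
    def totals(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix.T, columns=self.names).to_csv(path, sep="\t", index_label="site")

    @staticmethod
    def from_tsv(path) -> "SiteLnLMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return SiteLnLMatrix(names=list(frame.columns), matrix=frame.to_numpy().T)


def site_lnl_matrix(
    aln: Alignment,
    candidates: list[tuple[str, object]],
    model: SubstModel | dict[str, SubstModel],
) -> SiteLnLMatrix:
    """Per-site log-likelihood of every column under every candidate tree.

    With a partitioned model dict, each partition's columns are scored under
    its own model.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate trees")
    rows = []
    for name, tree in candidates:
        if isinstance(model, dict):
            row = np.empty(aln.n_cols)
            for pname, mdl in model.items():
                cols = aln.partitions[pname]
                row[cols] = site_likelihoods(aln, tree, mdl, cols=cols).site_lnl
        else:
            row = site_likelihoods(aln, tree, model).site_lnl
        rows.append(row)
    return SiteLnLMatrix(
        names=[n for n, _ in candidates],
        matrix=np.vstack(rows),
        alignment_checksum=aln.checksum(),
    )


def rell_resample(
    m: SiteLnLMatrix, n_reps: int, scale: float = 1.0, seed: int = 0
) -> np.ndarray:
    """Replicate totals (n_reps, n_candidates) at resampling scale ``scale``.

    Each replicate draws ceil(scale * n_sites) columns with replacement; the
    same column draw is shared by all candidates.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if scale <= 0:
        raise ValueError("scale must be positive")
    rng = rng_for(seed, f"rell:{scale:g}")
    n_sites = m.n_sites
    n_draw = int(np.ceil(scale * n_sites))
    counts = rng.multinomial(n_draw, np.full(n_sites, 1.0 / n_sites), size=n_reps)
    return counts.astype(float) @ m.matrix.T


def _pairwise_sd(R: np.ndarray) -> np.ndarray:
    """sd over replicates of R[:, j] - R[:, i] for all pairs, (n, n)."""
    cov = np.cov(R.T, ddof=1) if R.shape[1] > 1 else np.zeros((1, 1))
    var = np.diag(cov)
    s2 = var[None, :] + var[:, None] - 2.0 * cov
    return np.sqrt(np.clip(s2, 0.0, None))


def kh_sh_tests(
    m: SiteLnLMatrix, n_reps: int = 10_000, weighted: bool = True, seed: int = 0
) -> pd.DataFrame:
    """KH and SH p-values (weighted by default) per candidate.

    Returns a frame indexed by candidate with columns ``lnl``, ``delta``,
    ``p_kh``, ``p_sh`` (named ``p_wkh``/``p_wsh`` when weighted).  Zero
    variance differences (identical rows) yield p = 1 by convention.
    """
    L = m.totals
    k = int(np.argmax(L))
    T = rell_resample(m, n_reps, scale=1.0, seed=seed)
    R = T - T.mean(axis=0, keepdims=True)
    nc = len(L)
    s = _pairwise_sd(R) if weighted else np.ones((nc, nc))
    eps = 1e-12

    p_kh = np.empty(nc)
    p_sh = np.empty(nc)
    for i in range(nc):
        d_obs = L[k] - L[i]
        sd_ik = s[i, k]
        if sd_ik < eps:
            z_obs = 0.0 if d_obs <= eps else np.inf
        else:
            z_obs = d_obs / sd_ik
        null_k = (R[:, k] - R[:, i]) / (sd_ik if sd_ik >= eps else 1.0)
        p_kh[i] = np.mean(null_k >= z_obs - 1e-12)
        with np.errstate(invalid="ignore", divide="ignore"):
            Z = (R - R[:, [i]]) / np.where(s[i] < eps, np.nan, s[i])[None, :]
        Z[:, i] = 0.0  # own term: standardized difference is identically 0
        Z = np.where(np.isnan(Z), 0.0, Z)
        null_max = Z.max(axis=1)
        p_sh[i] = np.mean(null_max >= z_obs - 1e-12)

    tag = "w" if weighted else ""
    return pd.DataFrame(
        {
            "lnl": L,
            "delta": L[k] - L,
            f"p_{tag}kh": p_kh,
            f"p_{tag}sh": p_sh,
        },
        index=pd.Index(m.names, name="candidate"),
    )


def au_test(
    m: SiteLnLMatrix,
    scales=DEFAULT_AU_SCALES,
    n_reps: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Approximately unbiased p-value per candidate via multiscale bootstrap.

    Requires at least 3 scales spanning values below and above 1.  Bootstrap
    probabilities of 0 or 1 at a scale get the continuity correction
    1/(2 n_reps); if a candidate is (never | always) best at every scale the
    fit is degenerate and p is reported as (0 | 1) with ``degenerate=True``.
    """
    scales = np.asarray(scales, dtype=float)
    if len(scales) < 3 or scales.min() >= 1.0 or scales.max() <= 1.0:
        raise ValueError("need >= 3 scales spanning values below and above 1")
    nc = len(m.names)
    bp = np.empty((len(scales), nc))
    for si, r in enumerate(scales):
        T = rell_resample(m, n_reps, scale=float(r), seed=seed)
        best = T.max(axis=1, keepdims=True)
        is_best = np.isclose(T, best, rtol=0.0, atol=1e-9)
        bp[si] = (is_best / is_best.sum(axis=1, keepdims=True)).mean(axis=0)

    lo, hi = 1.0 / (2 * n_reps), 1.0 - 1.0 / (2 * n_reps)
    out = []
    for i in range(nc):
        b = bp[:, i]
        if np.all(b <= lo):
            out.append((0.0, np.nan, np.nan, True))
            continue
        if np.all(b >= hi):
            out.append((1.0, np.nan, np.nan, True))
            continue
        bc = np.clip(b, lo, hi)
        z = norm.ppf(1.0 - bc)
        X = np.column_stack([np.sqrt(scales), 1.0 / np.sqrt(scales)])
        w = n_reps * norm.pdf(z) ** 2 / (bc * (1.0 - bc))
        WX = X * w[:, None]
        beta = np.linalg.solve(X.T @ WX, WX.T @ z)
        d, c = beta
        out.append((float(norm.sf(d - c)), float(d), float(c), False))

    return pd.DataFrame(
        out,
        columns=["p_au", "d", "c", "degenerate"],
        index=pd.Index(m.names, name="candidate"),
    )


@dataclass
class TopologyTestResult:
    """Combined battery result for a candidate set."""

    table: pd.DataFrame  # candidate rows: lnl, delta, p_wkh, p_au, p_wsh
    n_reps: int
    scales: tuple
    seed: int


def run_topology_tests(
    m: SiteLnLMatrix,
    n_reps: int = 10_000,
    au_reps: int = 2000,
    scales=DEFAULT_AU_SCALES,
    seed: int = 0,
) -> TopologyTestResult:
    khsh = kh_sh_tests(m, n_reps=n_reps, weighted=True, seed=seed)
    au = au_test(m, scales=scales, n_reps=au_reps, seed=seed)
    table = khsh.join(au[["p_au"]])[["lnl", "delta", "p_wkh", "p_au", "p_wsh"]]
    return TopologyTestResult(table=table, n_reps=n_reps, scales=tuple(scales), seed=seed)


def test_report(result: TopologyTestResult, alpha: float = 0.05) -> str:
    """Render the battery as a table (columns wkh, au, wsh) plus a summary.

    P-values below ``alpha`` are flagged with '*'; when nothing is rejected
    the summary states so explicitly.
    """
    t = result.table
    if t.empty:
        raise ValueError("empty candidate list")
    lines = ["hypothesis\twkh\tau\twsh"]
    for name, row in t.iterrows():
        cells = [
            f"{row[c]:.3f}" + ("*" if row[c] < alpha else "")
            for c in ("p_wkh", "p_au", "p_wsh")
        ]
        lines.append("\t".join([str(name)] + cells))
    rejected = t[(t[["p_wkh", "p_au", "p_wsh"]] < alpha).any(axis=1)]
    if rejected.empty:
        lines.append(f"no hypothesis rejected at {alpha:g}")
    else:
        lines.append(
            f"rejected at {alpha:g}: " + ", ".join(map(str, rejected.index.tolist()))
        )
    return "\n".join(lines)
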