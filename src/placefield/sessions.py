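"""Cross-session place-field comparison: shifts, map retention, n_spec shifts.

Cells are matched across sessions by an externally supplied identity
table (ROI registration is out of scope).  Only cells with exactly one
field in both sessions enter the shift statistics; a cognitive map is
called retained when the distribution of field shifts is consistent with
a sharp zero-centred normal rather than dispersed over the circle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CellMatch",
    "FieldShift",
    "RetentionResult",
    "signed_circular_diff",
    "field_shifts",
    "retention_test",
    "nspec_shift_analysis",
]


@dataclass(frozen=True)
class CellMatch:
    """One-to-one cell-identity mapping between two sessions."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        a = [p[0] for p in self.pairs]
        b = [p[1] for p in self.pairs]
        if len(set(a)) != len(a) or len(set(b)) != len(b):
            raise ValueError("cell match must be one-to-one")


@dataclass(frozen=True)
class FieldShift:
    cell_a: int
    cell_b: int
    shift_bins: float  # signed minimal circular difference, in [-n/2, n/2)
    nspec_shift: int | None = None  # n_spec(B) - n_spec(A) when known


@dataclass
class RetentionResult:
    p_value: float
    retained: bool
    n: int
    underpowered: bool
    degenerate: bool = False
    logic: str = "conventional"


def signed_circular_diff(b: float, a: float, n_bins: int) -> float:
    """Signed minimal circular difference b - a in bin units, in [-n/2, n/2)."""
    return float(np.mod(b - a + n_bins / 2.0, n_bins) - n_bins / 2.0)


def field_shifts(
    centers_a: dict[int, list[float]],
    centers_b: dict[int, list[float]],
    match: CellMatch,
    n_bins: int = 20,
    nspec_a: dict[int, int] | None = None,
    nspec_b: dict[int, int] | None = None,
) -> tuple[list[FieldShift], list[tuple[int, int]]]:
    """Shifts for matched single-field place cells.

    ``centers_*`` map cell id -> list of field centers (bin units) for the
    cells that are place cells in that session.  Returns the shift list
    and, separately, matched pairs that are a place cell in exactly one
    session (the "not a place cell" transition category).
    """
    shifts: list[FieldShift] = []
    one_sided: list[tuple[int, int]] = []
    for ca, cb in match.pairs:
        in_a, in_b = ca in centers_a, cb in centers_b
        if in_a != in_b:
            one_sided.append((ca, cb))
            continue
        if not (in_a and in_b):
            continue
        fa, fb = centers_a[ca], centers_b[cb]
        if len(fa) != 1 or len(fb) != 1:
            continue  # multi-field cells excluded from shift statistics
        ns = None
        if nspec_a is not None and nspec_b is not None:
            if ca in nspec_a and cb in nspec_b:
                ns = int(nspec_b[cb]) - int(nspec_a[ca])
        shifts.append(
            FieldShift(ca, cb, signed_circular_diff(fb[0], fa[0], n_bins), ns)
        )
    return shifts, one_sided


def retention_test(
    shifts: list[FieldShift] | np.ndarray,
    n_bins: int = 20,
    alpha: float = 0.05,
    logic: str = "conventional",
    min_expected: float = 0.5,
) -> RetentionResult:
    """Chi-square goodness of fit of the shift histogram to a zero-mean normal.

    Shifts are binned into the track's own signed integer bins; the null
    is a zero-mean normal truncated to the circular support, its sd
    estimated from the observed shifts.  Adjacent bins are merged until
    each expected count reaches ``min_expected`` (kept low: the tail
    bins, where a dispersed remapped distribution departs most from the
    peaked null, carry most of the discriminative power).
    ``logic="conventional"`` calls the map retained when the test fails
    to reject normality (p > alpha); ``logic="inverted"`` uses the
    opposite direction (retained when p < alpha), occasionally seen in
    the literature.
    """
    if logic not in ("conventional", "inverted"):
        raise ValueError("logic must be 'conventional' or 'inverted'")
    if isinstance(shifts, (list, tuple)) and shifts and isinstance(shifts[0], FieldShift):
        vals = np.array([s.shift_bins for s in shifts], dtype=float)
    else:
        vals = np.asarray(shifts, dtype=float)
    n = vals.size
    underpowered = n < 10
    if underpowered:
        warnings.warn("fewer than 10 shifts; retention test underpowered",
                      RuntimeWarning, stacklevel=2)
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    if sd == 0.0:
        # all shifts identical (e.g. exactly 0): trivially a point mass at zero
        retained = bool(n and abs(vals[0]) < 1e-12)
        return RetentionResult(
            p_value=float("nan"), retained=retained, n=n,
            underpowered=underpowered, degenerate=True, logic=logic,
        )

    half = n_bins // 2
    edges = np.arange(-half, half + 1, dtype=float)  # unit-bin histogram
    obs, _ = np.histogram(vals, bins=edges)
    # zero-mean normal truncated to the circular support [-n/2, n/2)
    cdf = stats.norm(loc=0.0, scale=sd).cdf
    p_edges = cdf(edges)
    probs = np.diff(p_edges)
    probs /= probs.sum()
    exp = probs * n

    # merge adjacent bins until every expected count reaches min_expected
    obs_m, exp_m = [], []
    acc_o, acc_e = 0.0, 0.0
    for o, e in zip(obs, exp):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            obs_m.append(acc_o)
            exp_m.append(acc_e)
            acc_o, acc_e = 0.0, 0.0
    if acc_e > 0:
        if exp_m:
            obs_m[-1] += acc_o
            exp_m[-1] += acc_e
        else:
            obs_m, exp_m = [acc_o], [acc_e]
    obs_a = np.array(obs_m)
    exp_a = np.array(exp_m) * (obs_a.sum() / np.sum(exp_m))

    k = obs_a.size
    ddof = 1  # sd estimated from the data
    if k - 1 - ddof < 1:
        # too few usable bins: cannot distinguish; call retained, flag degenerate
        return RetentionResult(
            p_value=float("nan"), retained=(logic == "conventional"), n=n,
            underpowered=True, degenerate=True, logic=logic,
        )
    chi2 = float(np.sum((obs_a - exp_a) ** 2 / exp_a))
    p = float(stats.chi2.sf(chi2, df=k - 1 - ddof))
    retained = (p < alpha) if logic == "inverted" else (p > alpha)
    return RetentionResult(
        p_value=p, retained=retained, n=n, underpowered=underpowered, logic=logic,
    )


def nspec_shift_analysis(
    shifts_retained: np.ndarray | list[float],
    shifts_remapped: np.ndarray | list[float],
):
    """Unpaired two-sample t-test of n_spec shifts, retained vs remapped group.

    Returns the scipy result object (statistic, pvalue); the sign of the
    statistic follows (retained - remapped).
    """
    a = np.asarray(shifts_retained, dtype=float)
    b = np.asarray(shifts_remapped, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    return stats.ttest_ind(a, b)
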