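"""Population mean comparison: one-way ANOVA, Tukey-Kramer, letter display.

Per-family copy numbers (or relative quantities) are compared across
populations with a classical fixed-effects one-way ANOVA.  Only when the
ANOVA is significant at ``alpha`` are all-pairs Tukey comparisons computed
(Tukey-Kramer harmonic form for unequal group sizes) and summarized as a
compact letter display: populations share a letter iff their pairwise
difference is non-significant, so the letters over a bar chart encode the
full post-hoc result.

The studentized-range distribution comes from scipy; the sums of squares,
the Tukey-Kramer standard errors and the insert-and-absorb letter algorithm
are implemented here.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import UndefinedStatisticError, ValidationError

__all__ = [
    "AnovaResult",
    "PairwiseComparisons",
    "one_way_anova",
    "tukey_kramer",
    "letter_display",
    "compare_populations",
]


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float


@dataclass
class PairwiseComparisons:
    """All-pairs Tukey results in a fixed group order."""

    groups: list[str]
    means: dict[str, float]
    alpha: float
    table: dict[frozenset, dict] = field(default_factory=dict)
    # table[{g1,g2}] = {"diff": .., "q": .., "p_value": .., "significant": bool}

    def significant(self, a: str, b: str) -> bool:
        return self.table[frozenset((a, b))]["significant"]

    def significance_flags(self) -> dict[frozenset, bool]:
        return {pair: rec["significant"] for pair, rec in self.table.items()}


def _check_groups(groups: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(list(vals), dtype=float)
        if arr.size < 2:
            raise ValidationError(f"group {name!r} needs at least two values")
        out[name] = arr
    if all(np.ptp(arr) == 0 for arr in out.values()):
        raise UndefinedStatisticError("all groups are internally constant: zero within-group variance")
    return out


def _sums_of_squares(groups: dict[str, np.ndarray]) -> tuple[float, float, int, int]:
    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in groups.values())
    ssw = sum(((a - a.mean()) ** 2).sum() for a in groups.values())
    k = len(groups)
    return float(ssb), float(ssw), k - 1, len(all_vals) - k


def one_way_anova(groups: dict[str, "np.ndarray | list[float]"]) -> AnovaResult:
    """Classical fixed-effects F test, F = MSB / MSW."""
    groups = _check_groups(groups)
    ssb, ssw, dfb, dfw = _sums_of_squares(groups)
    msb, msw = ssb / dfb, ssw / dfw
    f = msb / msw
    p = float(stats.f.sf(f, dfb, dfw))
    return AnovaResult(f_statistic=float(f), df_between=dfb, df_within=dfw, p_value=p)


def tukey_kramer(groups: dict[str, "np.ndarray | list[float]"],
                 alpha: float = 0.05) -> PairwiseComparisons:
    """All-pairs studentized-range comparisons (Tukey-Kramer for unequal n).

    For groups i, j: ``q = |m_i - m_j| / sqrt(MSW/2 * (1/n_i + 1/n_j))``
    with p from the studentized range distribution on (k, df_within).
    """
    groups = _check_groups(groups)
    _, ssw, _, dfw = _sums_of_squares(groups)
    msw = ssw / dfw
    k = len(groups)
    names = list(groups)
    means = {g: float(groups[g].mean()) for g in names}
    comp = PairwiseComparisons(groups=names, means=means, alpha=alpha)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = names[i], names[j]
            na, nb = len(groups[a]), len(groups[b])
            se = np.sqrt(msw / 2.0 * (1.0 / na + 1.0 / nb))
            q = abs(means[a] - means[b]) / se
            p = float(stats.studentized_range.sf(q, k, dfw))
            comp.table[frozenset((a, b))] = {
                "diff": means[a] - means[b],
                "q": float(q),
                "p_value": p,
                "significant": p < alpha,
            }
    return comp


def letter_display(
    comparisons: "PairwiseComparisons | dict[frozenset, bool]",
    groups: list[str] | None = None,
    order_by_mean: bool = True,
) -> dict[str, str]:
    """Compact letter display by the insert-and-absorb algorithm.

    Groups sharing a letter are mutually non-significant; every
    non-significant pair shares at least one letter.  Letters are assigned
    in descending order of group means when means are available (figure
    convention), otherwise in the given group order.
    """
    if isinstance(comparisons, PairwiseComparisons):
        flags = comparisons.significance_flags()
        names = list(comparisons.groups)
        if order_by_mean:
            names.sort(key=lambda g: -comparisons.means[g])
    else:
        flags = dict(comparisons)
        if groups is None:
            raise ValidationError("group order required when passing raw significance flags")
        names = list(groups)
    for a_i, a in enumerate(names):
        for b in names[a_i + 1:]:
            if frozenset((a, b)) not in flags:
                raise ValidationError(f"missing comparison for pair ({a!r}, {b!r})")

    # insert-and-absorb: start from one all-inclusive letter column; for
    # every significant pair, split each column containing both members
    # into two (dropping one member each), then absorb subset columns
    columns: list[set[str]] = [set(names)]
    for pair, significant in flags.items():
        if not significant:
            continue
        a, b = tuple(pair)
        nxt: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                nxt.append(col - {a})
                nxt.append(col - {b})
            else:
                nxt.append(col)
        columns = [c for c in nxt if c]
        columns = [c for c in columns if not any(c < d for d in columns)]
    unique: list[set[str]] = []
    for s in columns:
        if s not in unique:
            unique.append(s)
    # order letter sets by first member in display order
    pos = {g: i for i, g in enumerate(names)}
    unique.sort(key=lambda s: min(pos[g] for g in s))
    alphabet = string.ascii_lowercase
    out = {g: "" for g in names}
    for idx, s in enumerate(unique):
        ch = alphabet[idx] if idx < 26 else f"({idx})"
        for g in names:
            if g in s:
                out[g] += ch
    return out


def compare_populations(
    groups: dict[str, "np.ndarray | list[float]"], alpha: float = 0.05
) -> tuple[AnovaResult, PairwiseComparisons | None, dict[str, str]]:
    """ANOVA-gated Tukey comparison with letter summary.

    The post hoc test runs only when the ANOVA is significant at ``alpha``;
    otherwise every group shares the single letter "a".
    """
    anova = one_way_anova(groups)
    if anova.p_value < alpha:
        comp = tukey_kramer(groups, alpha=alpha)
        return anova, comp, letter_display(comp)
    names = sorted(groups, key=lambda g: -float(np.mean(np.asarray(list(groups[g]), dtype=float))))
    return anova, None, {g: "a" for g in names}
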