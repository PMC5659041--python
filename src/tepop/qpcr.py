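"""Relative and absolute qPCR quantification via the comparative Ct method.

Target quantity in each accession is normalized to a single-copy reference
gene (VRN1 for genomic copy number; Actin for expression work, the
machinery is identical) and to one designated reference sample:

    ddCt = (Ct_target - Ct_refgene)_sample - (Ct_target - Ct_refgene)_refsample
    RQ   = (2 * E)^(-ddCt)

with the amplification efficiency E expressed as a fraction of 1 (E = 1 is
perfect doubling, giving the familiar 2^-ddCt).  The ``(2 * E)`` base is
the package default; ``mode="conventional"`` switches to the textbook
``(1 + E)`` base — the two coincide only at E = 1.

Absolute copy numbers for short elements are calibrated against a genome
with a known per-family count (hexaploid bread wheat).  Because RQ measures
target per reference-gene copy, each genome's RQ is first rescaled by its
VRN1 dose — 2 copies in a tetraploid, 3 in a hexaploid — before taking the
cross-species ratio:

    cn = (RQ_sample * vrn1_sample) / (RQ_calibrator * vrn1_calibrator) * cn_calibrator
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError, ValidationError
from .marker_matrix import PopulationMap

__all__ = [
    "CtTable",
    "RelativeQuantity",
    "read_ct_table",
    "write_ct_table",
    "primer_efficiency",
    "mean_ct",
    "delta_delta_ct",
    "relative_quantity",
    "relative_quantities",
    "absolute_copy_number",
    "population_summary",
]

#: replicate Ct spread above this many cycles triggers a QC warning
CT_SPREAD_WARN = 0.5


@dataclass
class CtTable:
    """Replicate qPCR threshold cycles with designated references.

    ``data`` holds one row per (accession, target) with a list of replicate
    Ct values.  ``reference_gene`` is the single-copy normalizer (VRN1 or
    Actin); ``reference_sample`` the accession whose RQ is defined as 1.
    """

    records: list[tuple[str, str, list[float]]]
    reference_gene: str
    reference_sample: str

    _index: dict[tuple[str, str], list[float]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for acc, target, reps in self.records:
            reps = [float(r) for r in reps]
            if not reps:
                raise ValidationError(f"no replicate Ct for ({acc!r}, {target!r})")
            if any(r <= 0 for r in reps):
                raise ValidationError(f"non-positive Ct for ({acc!r}, {target!r})")
            key = (acc, target)
            if key in self._index:
                raise ValidationError(f"duplicate record for ({acc!r}, {target!r})")
            self._index[key] = reps
        for acc in self.accessions:
            if (acc, self.reference_gene) not in self._index:
                raise ValidationError(
                    f"reference gene {self.reference_gene!r} not measured for {acc!r}"
                )

    @property
    def accessions(self) -> list[str]:
        seen: dict[str, None] = {}
        for acc, _, _ in self.records:
            seen.setdefault(acc, None)
        return list(seen)

    @property
    def targets(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, target, _ in self.records:
            if target != self.reference_gene:
                seen.setdefault(target, None)
        return list(seen)

    def replicates(self, accession: str, target: str) -> list[float]:
        try:
            return self._index[(accession, target)]
        except KeyError:
            raise ValidationError(
                f"no Ct measurement for accession {accession!r}, target {target!r}"
            ) from None


def read_ct_table(source: str | Path, reference_gene: str, reference_sample: str,
                  sep: str | None = None) -> CtTable:
    """Read a long-format Ct table (accession, target, replicate, ct)."""
    sep = sep or ("," if str(source).endswith(".csv") else "\t")
    df = pd.read_csv(source, sep=sep, comment="#")
    needed = {"accession", "target", "ct"}
    if not needed.issubset(df.columns):
        raise ValidationError(f"Ct table must have columns {sorted(needed)}")
    records = [
        (str(acc), str(target), grp["ct"].astype(float).tolist())
        for (acc, target), grp in df.groupby(["accession", "target"], sort=False)
    ]
    return CtTable(records, reference_gene=reference_gene, reference_sample=reference_sample)


def write_ct_table(table: CtTable, sink: str | Path | io.TextIOBase, sep: str = "\t") -> None:
    rows = []
    for acc, target, reps in table.records:
        for k, ct in enumerate(reps, start=1):
            rows.append({"accession": acc, "target": target, "replicate": k, "ct": ct})
    pd.DataFrame(rows).to_csv(sink, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Elementary quantities
# ---------------------------------------------------------------------------

def primer_efficiency(slope: float) -> float:
    """Amplification efficiency from a standard-curve slope.

    ``E = 10^(-1/slope) - 1`` as a fraction of 1 (1.0 is 100%: a slope of
    about -3.32 cycles per 10-fold dilution).  Values far outside the usual
    assay range trigger a warning but are returned unchanged.
    """
    if slope >= 0:
        raise ValidationError("standard-curve slope must be negative")
    eff = 10.0 ** (-1.0 / slope) - 1.0
    if not 0.8 <= eff <= 1.1:
        warnings.warn(f"primer efficiency {eff:.3f} outside the usual [0.8, 1.1] range")
    return eff


def mean_ct(replicates: Sequence[float]) -> tuple[float, float]:
    """Mean and sample SD (ddof=1) of replicate Cts; SD is 0 for n = 1."""
    reps = np.asarray(list(replicates), dtype=float)
    if reps.size == 0:
        raise ValidationError("no replicate Ct values")
    mean = float(reps.mean())
    if reps.size == 1:
        warnings.warn("single Ct replicate: standard deviation undefined, reported as 0")
        return mean, 0.0
    if reps.max() - reps.min() > CT_SPREAD_WARN:
        warnings.warn(
            f"replicate Ct spread {reps.max() - reps.min():.2f} cycles exceeds "
            f"{CT_SPREAD_WARN} (QC)"
        )
    return mean, float(reps.std(ddof=1))


def delta_delta_ct(table: CtTable, target: str, accession: str,
                   reference_gene: str | None = None,
                   reference_sample: str | None = None) -> float:
    """ddCt of one accession/target pair against the table's references."""
    ref_gene = reference_gene or table.reference_gene
    ref_sample = reference_sample or table.reference_sample
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ct_t_s, _ = mean_ct(table.replicates(accession, target))
        ct_r_s, _ = mean_ct(table.replicates(accession, ref_gene))
        ct_t_ref, _ = mean_ct(table.replicates(ref_sample, target))
        ct_r_ref, _ = mean_ct(table.replicates(ref_sample, ref_gene))
    return (ct_t_s - ct_r_s) - (ct_t_ref - ct_r_ref)


def relative_quantity(ddct: float, efficiency: float = 1.0, mode: str = "doubling") -> float:
    """RQ from ddCt: ``(2 * E)^(-ddCt)`` (default) or ``(1 + E)^(-ddCt)``.

    ``mode="doubling"`` takes the amplification base literally as twice the
    efficiency fraction (E = 1 gives base 2); ``mode="conventional"`` uses
    the textbook ``1 + E`` base.  The two agree only at E = 1.
    """
    if not 0.0 < efficiency <= 1.25:
        raise ValidationError("efficiency must lie in (0, 1.25]")
    if mode == "doubling":
        base = 2.0 * efficiency
    elif mode == "conventional":
        base = 1.0 + efficiency
    else:
        raise ValidationError(f"unknown efficiency mode {mode!r}")
    if base <= 0:
        raise ValidationError("non-positive amplification base")
    return base ** (-ddct)


def relative_quantities(table: CtTable, efficiency: float = 1.0,
                        mode: str = "doubling") -> pd.DataFrame:
    """Per-accession RQ for every target in the table.

    Returns a tidy frame (accession, target, ddct, rq, ct_sd) where
    ``ct_sd`` is the replicate SD of the target Ct for that accession.  The
    reference sample's rq is exactly 1 for every target by construction.
    """
    rows = []
    for target in table.targets:
        for acc in table.accessions:
            if (acc, target) not in table._index:
                continue
            ddct = delta_delta_ct(table, target, acc)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, sd = mean_ct(table.replicates(acc, target))
            rows.append(
                {
                    "accession": acc,
                    "target": target,
                    "ddct": ddct,
                    "rq": relative_quantity(ddct, efficiency, mode),
                    "ct_sd": sd,
                }
            )
    return pd.DataFrame(rows)


def absolute_copy_number(
    rq_sample: float,
    rq_calibrator: float,
    calibrator_cn: float,
    vrn1_copies_sample: int = 2,
    vrn1_copies_calibrator: int = 3,
) -> float:
    """Absolute per-genome copy number against a sequenced calibrator.

    RQ counts target per reference-gene copy, so each genome's total is RQ
    times its VRN1 dose (2 for the tetraploid sample, 3 for the hexaploid
    calibrator); the ratio of these totals scales the calibrator's known
    count.  ``absolute_copy_number(r, r, cn, 3, 3) == cn`` by construction.
    """
    if rq_sample < 0 or rq_calibrator <= 0:
        raise ValidationError("relative quantities must be positive")
    if calibrator_cn < 0:
        raise ValidationError("calibrator copy number must be non-negative")
    return (rq_sample * vrn1_copies_sample) / (rq_calibrator * vrn1_copies_calibrator) * calibrator_cn


def population_summary(values: pd.DataFrame, popmap: PopulationMap,
                       value_col: str = "rq") -> pd.DataFrame:
    """Per-(target, population) mean and standard error of accession values.

    ``values`` is tidy with columns (accession, target, <value_col>).  SE is
    SD/sqrt(n) with ddof=1 (0 for n = 1).  Populations with no measured
    accession for a target are flagged with NaN, not an error.
    """
    popmap.check_covers(values["accession"].unique())
    rows = []
    for target, grp in values.groupby("target", sort=False):
        for pop in popmap.populations:
            accs = set(popmap.accessions_of(pop))
            sel = grp[grp["accession"].isin(accs)][value_col].astype(float)
            n = len(sel)
            if n == 0:
                rows.append({"target": target, "population": pop, "n": 0,
                             "mean": float("nan"), "se": float("nan")})
                continue
            se = 0.0 if n == 1 else float(sel.std(ddof=1) / math.sqrt(n))
            rows.append({"target": target, "population": pop, "n": n,
                         "mean": float(sel.mean()), "se": se})
    return pd.DataFrame(rows)
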