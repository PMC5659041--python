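"""Synthetic marker matrices and Ct tables with population structure.

No raw band matrices or Ct tables were published for the study design this
package targets, so tests and examples run on simulated data whose shape
matches it: 5 populations x 10 accessions, 6 MITE families with 70-116
scored insertion sites each, per-population polymorphism spanning roughly
10-90%, and per-family mean copy numbers from tens to thousands.

Generative model for the presence/absence matrix, per family:

* *fixed* loci — ancestral insertions near fixation everywhere (presence
  probability ``fixed_presence_prob`` in every accession); these supply the
  monomorphic fraction that differentiates low- from high-polymorphism
  families;
* *shared drifting* loci — an ancestral presence probability ``p0`` drifts
  independently in each population to ``q ~ Beta(kappa * p0, kappa *
  (1 - p0))`` (small ``kappa`` = strong differentiation), and accessions
  draw Bernoulli(q);
* *private* loci — each population owns a block of loci present only there
  (probability ``private_presence_prob`` within the owner, 0 elsewhere),
  producing population-unique insertions.

Loci that end up observed in no accession are dropped, preserving the
marker-matrix invariant.  Excision is not modelled separately from
non-inheritance: both surface as a 0 call, just as on a gel.

The Ct model ties the simulated copy numbers to the qPCR pipeline: the
reference gene cycles at ``Normal(mu_ref, sigma)`` and the target at
``mu_ref - log_base(cn / cn_ref_sample)`` plus noise, base ``2 *
efficiency``, three replicates per reaction, so at sigma = 0 the ddCt
pipeline inverts the simulation exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .marker_matrix import MarkerMatrix, PopulationMap
from .qpcr import CtTable

__all__ = [
    "FamilyConfig",
    "SimConfig",
    "SimTruth",
    "simulate_marker_matrix",
    "simulate_ct_table",
    "paper_design_preset",
]

POPULATIONS = ("MtHermon", "Amiad", "Tabgha", "Jaba", "MtAmasa")
POP_PREFIX = {"MtHermon": "H", "Amiad": "A", "Tabgha": "T", "Jaba": "J", "MtAmasa": "M"}


@dataclass(frozen=True)
class FamilyConfig:
    """Locus-count design for one TE family.

    ``p0``/``kappa`` override the global drift parameters when set, letting
    families differ in how conserved their shared insertions are.
    """

    label: str
    n_fixed_loci: int
    n_shared_loci: int
    n_private_loci_per_population: int
    p0: float | None = None
    kappa: float | None = None

    @property
    def n_loci(self) -> int:
        return self.n_fixed_loci + self.n_shared_loci + 5 * self.n_private_loci_per_population


def _default_families() -> list[FamilyConfig]:
    # fixed-locus counts chosen so the expected monomorphic fraction per
    # family spans the low-to-high polymorphism range of a natural design
    return [
        FamilyConfig("Aison", 8, 81, 2),
        FamilyConfig("Eos", 25, 62, 1),
        FamilyConfig("Fortuna", 10, 55, 1),
        FamilyConfig("Minos", 60, 23, 1),
        FamilyConfig("Oleus", 49, 38, 1),
        FamilyConfig("Tantalos", 22, 84, 2),
    ]


def _default_copy_numbers() -> dict[tuple[str, str], float]:
    # per-(family, population) true mean copy numbers, spanning tens
    # (Tantalos) to thousands (Aison/Eos) as in a wild-wheat MITE census
    table = {
        "Aison": {"MtHermon": 2100, "Amiad": 3528, "Tabgha": 1224, "Jaba": 1210, "MtAmasa": 2000},
        "Eos": {"MtHermon": 5305, "Amiad": 2104, "Tabgha": 5417, "Jaba": 3600, "MtAmasa": 3400},
        "Fortuna": {"MtHermon": 700, "Amiad": 820, "Tabgha": 450, "Jaba": 1003, "MtAmasa": 384},
        "Minos": {"MtHermon": 2742, "Amiad": 2300, "Tabgha": 2150, "Jaba": 2400, "MtAmasa": 1989},
        "Oleus": {"MtHermon": 450, "Amiad": 470, "Tabgha": 202, "Jaba": 694, "MtAmasa": 250},
        "Tantalos": {"MtHermon": 87, "Amiad": 45, "Tabgha": 52, "Jaba": 37, "MtAmasa": 61},
    }
    return {(fam, pop): float(v) for fam, pops in table.items() for pop, v in pops.items()}


@dataclass
class SimConfig:
    """Parameters of the synthetic world; defaults mirror the target design."""

    n_populations: int = 5
    accessions_per_population: int = 10
    families: list[FamilyConfig] = field(default_factory=_default_families)
    ancestral_presence_prob: float = 0.5
    drift_concentration: float = 5.0
    private_presence_prob: float = 0.8
    fixed_presence_prob: float = 0.998
    ct_noise_sd: float = 0.1
    ct_reference_mean: float = 20.0
    true_copy_numbers: dict[tuple[str, str], float] = field(default_factory=_default_copy_numbers)
    efficiency: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_populations < 1 or self.accessions_per_population < 1:
            raise ValidationError("population and accession counts must be positive")
        if self.n_populations > len(POPULATIONS):
            raise ValidationError(f"at most {len(POPULATIONS)} populations are labelled")
        for p in (self.ancestral_presence_prob, self.private_presence_prob,
                  self.fixed_presence_prob):
            if not 0.0 < p < 1.0:
                raise ValidationError("presence probabilities must lie in (0, 1)")
        if self.drift_concentration <= 0:
            raise ValidationError("drift concentration must be positive")
        if self.ct_noise_sd < 0:
            raise ValidationError("Ct noise SD must be non-negative")
        if not self.families:
            raise ValidationError("at least one family must be configured")
        for fam in self.families:
            if fam.n_loci < 1:
                raise ValidationError(f"family {fam.label!r} has no loci")

    @property
    def populations(self) -> list[str]:
        return list(POPULATIONS[: self.n_populations])

    def accession_ids(self) -> tuple[list[str], PopulationMap]:
        ids, assign = [], {}
        for pop in self.populations:
            for k in range(1, self.accessions_per_population + 1):
                acc = f"{POP_PREFIX[pop]}{k}"
                ids.append(acc)
                assign[acc] = pop
        return ids, PopulationMap(assign)


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated data set."""

    population_of: dict[str, str]
    locus_class: dict[str, str]            # design class: fixed/shared/private:<pop>
    true_copy_number: pd.DataFrame | None  # tidy: accession, target, cn

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"locus": l, "class": c} for l, c in self.locus_class.items()]
        )


def simulate_marker_matrix(config: SimConfig) -> tuple[MarkerMatrix, PopulationMap, SimTruth]:
    """Draw a presence/absence matrix under the configured population model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    ids, popmap = config.accession_ids()
    n_per = config.accessions_per_population
    pops = config.populations
    columns: dict[str, np.ndarray] = {}
    family_of: dict[str, str] = {}
    locus_class: dict[str, str] = {}
    for fam in config.families:
        p0 = fam.p0 if fam.p0 is not None else config.ancestral_presence_prob
        kappa = fam.kappa if fam.kappa is not None else config.drift_concentration
        counter = 0
        def add(col: np.ndarray, cls: str) -> None:
            nonlocal counter
            counter += 1
            locus = f"{fam.label}_{counter:03d}"
            columns[locus] = col
            family_of[locus] = fam.label
            locus_class[locus] = cls
        for _ in range(fam.n_fixed_loci):
            col = rng.binomial(1, config.fixed_presence_prob, size=len(ids))
            add(col, "fixed")
        for _ in range(fam.n_shared_loci):
            qs = rng.beta(kappa * p0, kappa * (1 - p0), size=len(pops))
            col = np.concatenate(
                [rng.binomial(1, q, size=n_per) for q in qs]
            )
            add(col, "shared")
        for pop_i, pop in enumerate(pops):
            for _ in range(fam.n_private_loci_per_population):
                col = np.zeros(len(ids), dtype=int)
                block = slice(pop_i * n_per, (pop_i + 1) * n_per)
                col[block] = rng.binomial(1, config.private_presence_prob, size=n_per)
                add(col, f"private:{pop}")
    df = pd.DataFrame(columns, index=ids)
    observed = df.columns[(df.sum(axis=0) > 0)]
    dropped = set(df.columns) - set(observed)
    df = df[observed]
    family_of = {l: f for l, f in family_of.items() if l not in dropped}
    locus_class = {l: c for l, c in locus_class.items() if l not in dropped}
    matrix = MarkerMatrix(df, family_of_locus=family_of)
    truth = SimTruth(population_of=dict(popmap.assignments),
                     locus_class=locus_class, true_copy_number=None)
    return matrix, popmap, truth


def simulate_ct_table(config: SimConfig) -> tuple[CtTable, SimTruth]:
    """Draw replicate Ct values consistent with the configured copy numbers.

    The reference sample is the first accession of the second population
    (or of the first when only one is configured); every family's Ct is
    expressed relative to that accession's true copy number, so the ddCt
    pipeline recovers the configured ratios up to Ct noise.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ids, popmap = config.accession_ids()
    pops = config.populations
    ref_pop = pops[1] if len(pops) > 1 else pops[0]
    reference_sample = f"{POP_PREFIX[ref_pop]}1"
    families = [f.label for f in config.families]
    missing = [
        (fam, pop) for fam in families for pop in pops
        if (fam, pop) not in config.true_copy_numbers
    ]
    if missing:
        raise ValidationError(f"true_copy_numbers missing entries: {missing[:5]}")
    base = 2.0 * config.efficiency
    if base <= 1.0:
        raise ValidationError("amplification base must exceed 1")
    mu_ref = config.ct_reference_mean
    sigma = config.ct_noise_sd
    records: list[tuple[str, str, list[float]]] = []
    truth_rows = []
    for acc in ids:
        reps = (mu_ref + rng.normal(0.0, sigma, size=3)).tolist()
        records.append((acc, "VRN1", reps))
    for fam in families:
        cn_ref = config.true_copy_numbers[(fam, popmap.population_of(reference_sample))]
        for acc in ids:
            cn = config.true_copy_numbers[(fam, popmap.population_of(acc))]
            mu_t = mu_ref - np.log(cn / cn_ref) / np.log(base)
            reps = (mu_t + rng.normal(0.0, sigma, size=3)).tolist()
            records.append((acc, fam, reps))
            truth_rows.append({"accession": acc, "target": fam, "cn": cn})
    table = CtTable(records, reference_gene="VRN1", reference_sample=reference_sample)
    truth = SimTruth(
        population_of=dict(popmap.assignments),
        locus_class={},
        true_copy_number=pd.DataFrame(truth_rows),
    )
    return table, truth


def paper_design_preset(seed: int = 0) -> SimConfig:
    """The default synthetic world: 5 x 10 design, 6 families, preset copy numbers."""
    return SimConfig(seed=seed)
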