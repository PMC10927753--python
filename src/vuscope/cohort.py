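"""Descriptive cohort statistics and qualitative cosegregation evaluation.

The cohort stage summarises probands carrying gene variants (prevalence of
each ACMG class in the tested population, ages at diagnosis, tumour
phenotypes, family-history counts) and evaluates, family by family, whether
a variant travels with disease among the tested relatives.  Cosegregation
here is a qualitative tally — consistent / excluded / uninformative — not a
likelihood-ratio method: a single tested affected non-carrier excludes the
variant as the shared predisposition factor, while at least one additional
tested affected carrier (with no exclusion) is consistent with
cosegregation.

All displayed numbers round half-up; when computed summaries disagree with
previously reported figures for the same data, both are surfaced via
:func:`flag_discrepancies` rather than silently reconciled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .utils import round_half_up

CLASSIFICATIONS = ("P_LP", "VUS")
_CLASS_TOKENS = {
    "P_LP": "P_LP", "P/LP": "P_LP", "PLP": "P_LP", "PATHOGENIC": "P_LP",
    "VUS": "VUS",
}

REQUIRED_COLUMNS = (
    "family_id", "genotype_cdna", "classification", "age_at_diagnosis",
    "tumor_phenotype", "bilateral", "other_tumors", "bc_fdr", "bc_sdr",
    "other_family_tumors", "sex",
)


class CohortFormatError(ValueError):
    pass


class PedigreeError(ValueError):
    pass


@dataclass(frozen=True)
class CohortRecord:
    family_id: str
    genotype_cdna: str
    classification: str          # P_LP | VUS
    age_at_diagnosis: float
    tumor_phenotype: str
    bilateral: bool
    other_tumors: bool
    bc_fdr: int                  # breast cancers among first-degree relatives
    bc_sdr: int                  # ... second-degree relatives
    other_family_tumors: str
    sex: str                     # F | M

    def __post_init__(self):
        if self.age_at_diagnosis <= 0:
            raise CohortFormatError(
                f"family {self.family_id}: age must be positive")
        if self.bc_fdr < 0 or self.bc_sdr < 0:
            raise CohortFormatError(
                f"family {self.family_id}: negative relative counts")
        if self.classification not in CLASSIFICATIONS:
            raise CohortFormatError(
                f"family {self.family_id}: classification "
                f"{self.classification!r}")


@dataclass(frozen=True)
class Individual:
    id: str
    sex: str
    father: Optional[str]
    mother: Optional[str]
    affected: bool
    cancer_type: Optional[str] = None
    age_dx: Optional[float] = None
    tested: bool = False
    carrier: Optional[bool] = None     # None = unknown / untested


@dataclass
class Pedigree:
    family_id: str
    individuals: list[Individual]
    proband: str
    variant: Optional[str] = None

    def __post_init__(self):
        ids = {ind.id for ind in self.individuals}
        if len(ids) != len(self.individuals):
            raise PedigreeError("duplicate individual ids")
        if self.proband not in ids:
            raise PedigreeError(f"proband {self.proband!r} not in pedigree")
        for ind in self.individuals:
            for parent in (ind.father, ind.mother):
                if parent is not None and parent not in ids:
                    raise PedigreeError(
                        f"{ind.id}: parent {parent!r} unresolved")
        self._check_acyclic()

    def _check_acyclic(self):
        parents = {ind.id: [p for p in (ind.father, ind.mother) if p]
                   for ind in self.individuals}
        WHITE, GREY, BLACK = 0, 1, 2
        color = dict.fromkeys(parents, WHITE)

        def visit(node):
            color[node] = GREY
            for p in parents[node]:
                if color[p] == GREY:
                    raise PedigreeError("cyclic parentage")
                if color[p] == WHITE:
                    visit(p)
            color[node] = BLACK

        for node in parents:
            if color[node] == WHITE:
                visit(node)

    def get(self, ind_id: str) -> Individual:
        for ind in self.individuals:
            if ind.id == ind_id:
                return ind
        raise KeyError(ind_id)


@dataclass(frozen=True)
class CosegregationResult:
    family_id: str
    n_tested_affected_carriers: int      # relatives only, proband excluded
    n_tested_affected_noncarriers: int
    n_tested_unaffected_carriers: int
    verdict: str                         # consistent | excluded | uninformative


# ---------------------------------------------------------------------------
# I/O

def load_cohort(path: str | Path) -> list[CohortRecord]:
    """Read a cohort TSV (one proband per row) into typed records."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        token = row["classification"].strip().upper()
        if token not in _CLASS_TOKENS:
            raise CohortFormatError(f"unknown classification {token!r}")
        records.append(CohortRecord(
            family_id=row["family_id"],
            genotype_cdna=row["genotype_cdna"].strip(),
            classification=_CLASS_TOKENS[token],
            age_at_diagnosis=float(row["age_at_diagnosis"]),
            tumor_phenotype=row["tumor_phenotype"].strip(),
            bilateral=row["bilateral"].strip().lower() in ("yes", "true", "1"),
            other_tumors=row["other_tumors"].strip().lower() in ("yes", "true", "1"),
            bc_fdr=int(row["bc_fdr"]), bc_sdr=int(row["bc_sdr"]),
            other_family_tumors=str(row["other_family_tumors"]).strip(),
            sex=row["sex"].strip().upper()))
    return records


def load_pedigree(path: str | Path) -> Pedigree:
    """Read a pedigree JSON (individuals with parent links and test results)."""
    data = json.loads(Path(path).read_text())
    individuals = [Individual(
        id=d["id"], sex=d.get("sex", "U"), father=d.get("father"),
        mother=d.get("mother"), affected=bool(d.get("affected", False)),
        cancer_type=d.get("cancer_type"), age_dx=d.get("age_dx"),
        tested=bool(d.get("tested", False)), carrier=d.get("carrier"),
    ) for d in data["individuals"]]
    return Pedigree(family_id=str(data.get("family_id", "?")),
                    individuals=individuals, proband=data["proband"],
                    variant=data.get("variant"))


def packaged_fixture(name: str) -> Path:
    """Path to a bundled example data file (e.g. ``table1.tsv``)."""
    return Path(str(resources.files("vuscope").joinpath("data", name)))


# ---------------------------------------------------------------------------
# Statistics

def prevalence(records: Sequence[CohortRecord], n_tested: int,
               classification: str) -> float:
    """Percent of tested probands carrying a variant of ``classification``,
    rounded half-up to 2 dp."""
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    count = sum(1 for r in records if r.classification == classification)
    if count > n_tested:
        raise ValueError("more matching records than tested individuals")
    return round_half_up(100.0 * count / n_tested, 2)


def describe(records: Sequence[CohortRecord], classification: str) -> dict:
    """Summary of one classification subset: n, mean age (1 dp), age range,
    phenotype counts, bilateral count, FDR/SDR totals."""
    subset = [r for r in records if r.classification == classification]
    if not subset:
        return {"classification": classification, "n": 0, "empty": True}
    ages = [r.age_at_diagnosis for r in subset]
    phenotypes: dict[str, int] = {}
    for r in subset:
        phenotypes[r.tumor_phenotype] = phenotypes.get(r.tumor_phenotype, 0) + 1
    return {
        "classification": classification,
        "n": len(subset),
        "mean_age": round_half_up(sum(ages) / len(ages), 1),
        "age_range": (min(ages), max(ages)),
        "phenotype_counts": phenotypes,
        "bilateral_count": sum(r.bilateral for r in subset),
        "bc_fdr_total": sum(r.bc_fdr for r in subset),
        "bc_sdr_total": sum(r.bc_sdr for r in subset),
        "n_distinct_genotypes": len({r.genotype_cdna for r in subset}),
        "empty": False,
    }


def flag_discrepancies(computed: dict, published: dict,
                       tol: float = 1e-9) -> list[str]:
    """Compare computed summary values with previously reported ones.

    ``published`` maps keys of ``computed`` to reference values; every
    mismatch yields a flag string.  Computed values are never adjusted.
    """
    flags = []
    for key, ref in published.items():
        if key not in computed:
            continue
        got = computed[key]
        if isinstance(ref, (list, tuple)):
            if tuple(got) != tuple(ref):
                flags.append(f"{key}: computed {tuple(got)} != reported {tuple(ref)}")
        elif abs(float(got) - float(ref)) > tol:
            flags.append(f"{key}: computed {got} != reported {ref}")
    return flags


# ---------------------------------------------------------------------------
# Cosegregation

def cosegregation(ped: Pedigree) -> CosegregationResult:
    """Qualitative cosegregation verdict for one family.

    excluded: any tested affected relative is a non-carrier;
    consistent: no exclusion and at least one tested affected relative
    (besides the proband) carries the variant; uninformative otherwise.
    Untested individuals never influence the verdict.
    """
    proband = ped.get(ped.proband)
    if not proband.tested or proband.carrier is not True:
        raise PedigreeError("proband must be a tested carrier")
    aff_car = aff_non = unaff_car = 0
    for ind in ped.individuals:
        if ind.id == ped.proband or not ind.tested or ind.carrier is None:
            continue
        if ind.affected and ind.carrier:
            aff_car += 1
        elif ind.affected and not ind.carrier:
            aff_non += 1
        elif not ind.affected and ind.carrier:
            unaff_car += 1
    if aff_non > 0:
        verdict = "excluded"
    elif aff_car > 0:
        verdict = "consistent"
    else:
        verdict = "uninformative"
    return CosegregationResult(
        family_id=ped.family_id,
        n_tested_affected_carriers=aff_car,
        n_tested_affected_noncarriers=aff_non,
        n_tested_unaffected_carriers=unaff_car,
        verdict=verdict)
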