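"""Chemical-marker validation and molecular/chemical fusion.

Every marketed species has a pharmacopoeial specification: a designated
chemical marker (e.g. valerenic acid for valerian, apigenin 7-glucoside for
chamomile), a minimum concentration, and the assay that quantifies it (HPLC
or UV) after a TLC presence screen.  A sample is chemically valid when the
marker is present and its concentration is at or above the minimum — the
boundary is inclusive, so a measurement exactly at the minimum passes.

The fusion step combines the molecular verdict (similarity/barcode-gap
based) with the chemistry into a concordance colour:

* green   — molecular evidence matches the labelled species (authentic, or
            within the expected genus pending species resolution) and the
            TLC marker is present;
* yellow  — molecular substitute or unidentifiable, yet the marker is
            present: the sample would pass a chemistry-only control;
* red     — the marker is absent;
* missing — no sequence was obtained or the chemistry was not tested.

Hazard flags record the two safety-relevant discordances: a substitute that
meets the minimum concentration, and a correctly identified sample that
fails its chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_DOWN, ROUND_HALF_UP
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

MOLECULAR_VERDICTS = ("authentic", "substitute", "inconclusive", "unidentified", "no_sequence")
#: verdicts compatible with the labelled species (expected-side)
EXPECTED_SIDE = ("authentic", "inconclusive")

UNITS = ("percent", "mg_per_g")


class UnitMismatchError(ValueError):
    pass


@dataclass(frozen=True)
class ChemicalSpec:
    species: str
    marker_name: str
    min_concentration: float
    unit: str
    assay: str  # "HPLC" | "UV"
    tlc_required: bool = True

    def __post_init__(self) -> None:
        if self.min_concentration <= 0:
            raise ValueError("minimum concentration must be positive")
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")


@dataclass
class AssayResult:
    sample_id: str
    tlc_present: str  # "present" | "absent" | "not_tested"
    concentration: float | None
    unit: str | None = None


@dataclass
class EvaluatedAssay:
    presence: bool | None
    meets_minimum: bool | None
    flags: list[str] = field(default_factory=list)


def evaluate_assay(result: AssayResult, spec: ChemicalSpec) -> EvaluatedAssay:
    """Check TLC presence and the concentration against the species minimum."""
    if result.unit is not None and result.concentration is not None and result.unit != spec.unit:
        raise UnitMismatchError(
            f"{result.sample_id}: assay unit {result.unit!r} != spec unit {spec.unit!r}"
        )
    presence = {"present": True, "absent": False, "not_tested": None}[result.tlc_present]
    meets = None
    flags: list[str] = []
    if result.concentration is not None:
        meets = result.concentration >= spec.min_concentration
        if presence is False and meets:
            # never observed in practice: TLC-negative but quantified above minimum
            flags.append("tlc_hplc_inconsistent")
    return EvaluatedAssay(presence, meets, flags)


@dataclass
class MolecularCall:
    sample_id: str
    labelled_species: str
    verdict: str  # one of MOLECULAR_VERDICTS
    assigned_taxon: str | None = None
    rank: str | None = None

    def __post_init__(self) -> None:
        if self.verdict not in MOLECULAR_VERDICTS:
            raise ValueError(f"unknown molecular verdict {self.verdict!r}")


@dataclass
class AuthenticationRecord:
    sample_id: str
    labelled_species: str
    molecular_verdict: str
    assigned_taxon: str | None
    chemical_presence: bool | None
    meets_minimum: bool | None
    concordance: str  # "green" | "yellow" | "red" | "missing"
    hazard_flags: list[str] = field(default_factory=list)


def authenticate_sample(
    molecular: MolecularCall,
    assay: AssayResult | None,
    spec: ChemicalSpec | None,
) -> AuthenticationRecord:
    """Fuse one sample's molecular verdict with its evaluated chemistry."""
    evaluated = EvaluatedAssay(None, None)
    if assay is not None and spec is not None:
        evaluated = evaluate_assay(assay, spec)
    flags = list(evaluated.flags)
    verdict = molecular.verdict
    if verdict == "no_sequence" or evaluated.presence is None:
        concordance = "missing"
    elif not evaluated.presence:
        concordance = "red"
    elif verdict in EXPECTED_SIDE:
        concordance = "green"
    else:
        concordance = "yellow"
    if verdict == "substitute" and evaluated.meets_minimum:
        flags.append("substitute_passes_chemistry")
    if verdict in EXPECTED_SIDE and evaluated.presence is False:
        flags.append("authentic_fails_chemistry")
    if verdict in EXPECTED_SIDE and evaluated.meets_minimum is False:
        flags.append("authentic_fails_concentration")
    return AuthenticationRecord(
        sample_id=molecular.sample_id,
        labelled_species=molecular.labelled_species,
        molecular_verdict=verdict,
        assigned_taxon=molecular.assigned_taxon,
        chemical_presence=evaluated.presence,
        meets_minimum=evaluated.meets_minimum,
        concordance=concordance,
        hazard_flags=flags,
    )


def percentage(
    numerator: float, denominator: float, places: int = 2, convention: str = "half_up"
) -> float:
    """Format a fraction as a percentage with an explicit rounding convention."""
    if denominator == 0:
        raise ZeroDivisionError("empty denominator")
    rounding = {"half_up": ROUND_HALF_UP, "truncate": ROUND_DOWN}[convention]
    q = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(q.quantize(Decimal(1).scaleb(-places), rounding=rounding))


def protocol_success_rates(
    successes: Mapping[str, int], n_total: int, convention: str = "half_up"
) -> dict[str, float]:
    """Per-marker protocol success percentages out of all collected samples."""
    return {m: percentage(k, n_total, convention=convention) for m, k in successes.items()}


def attrition(n_collected: int, *losses: int) -> int:
    """Samples remaining after successive protocol losses (never negative)."""
    remaining = n_collected - sum(losses)
    if remaining < 0:
        raise ValueError("losses exceed the collected total")
    return remaining


@dataclass
class StudySummary:
    """Three-tier accounting: total -> sequenced -> conclusive.

    Percent inconclusive is computed on the sequenced denominator; percent
    substitute/authentic on the conclusive denominator (sequenced minus
    inconclusive), so the two always sum to 100% of conclusive samples.
    """

    n_total: int
    n_no_sequence: int
    n_sequenced: int
    n_inconclusive: int
    n_conclusive: int
    n_substitute: int
    n_authentic: int
    inconclusive_pct: float
    substitute_pct: float
    authentic_pct: float
    concordance_counts: dict[str, int]
    per_species: pd.DataFrame


def summarize_study(
    records: Sequence[AuthenticationRecord],
    convention: str = "half_up",
    unidentified_as_substitute: bool = True,
) -> StudySummary:
    """Study-level proportions over authentication records.

    Unidentifiable sequences (no database match above the cutoff) default to
    counting as substitutions in the conclusive tier: they demonstrably are
    not the labelled species.
    """
    if not records:
        raise ValueError("no records to summarize")
    df = pd.DataFrame(
        {
            "species": r.labelled_species,
            "verdict": r.molecular_verdict,
            "concordance": r.concordance,
        }
        for r in records
    )
    sub_verdicts = {"substitute"} | ({"unidentified"} if unidentified_as_substitute else set())

    def tiers(sub: pd.DataFrame) -> dict:
        n_total = len(sub)
        n_noseq = int((sub.verdict == "no_sequence").sum())
        n_seq = n_total - n_noseq
        n_inc = int((sub.verdict == "inconclusive").sum())
        if not unidentified_as_substitute:
            n_inc += int((sub.verdict == "unidentified").sum())
        n_subst = int(sub.verdict.isin(sub_verdicts).sum())
        n_auth = int((sub.verdict == "authentic").sum())
        n_concl = n_subst + n_auth
        return {
            "n_total": n_total,
            "n_no_sequence": n_noseq,
            "n_sequenced": n_seq,
            "n_inconclusive": n_inc,
            "n_conclusive": n_concl,
            "n_substitute": n_subst,
            "n_authentic": n_auth,
            "inconclusive_pct": percentage(n_inc, n_seq, convention=convention) if n_seq else float("nan"),
            "substitute_pct": percentage(n_subst, n_concl, convention=convention) if n_concl else float("nan"),
            "authentic_pct": percentage(n_auth, n_concl, convention=convention) if n_concl else float("nan"),
        }

    overall = tiers(df)
    per_species = pd.DataFrame(
        [{"species": sp, **tiers(g)} for sp, g in df.groupby("species", sort=True)]
    )
    concordance_counts = df.concordance.value_counts().to_dict()
    return StudySummary(
        **overall,
        concordance_counts=concordance_counts,
        per_species=per_species,
    )


# ---------------------------------------------------------------------------
# packaged fixtures: the printed chemistry table and its taxonomy


def _data_path(name: str):
    return resources.files("herbcode.data").joinpath(name)


def load_chem_specs() -> dict[str, ChemicalSpec]:
    """The eight marketed species' pharmacopoeial specifications."""
    df = pd.read_csv(_data_path("chem_specs.tsv"), sep="\t")
    return {
        row.species: ChemicalSpec(
            row.species, row.marker_name, float(row.min_concentration), row.unit, row.assay
        )
        for row in df.itertuples()
    }


def load_market_taxonomy() -> pd.DataFrame:
    return pd.read_csv(_data_path("market_taxonomy.tsv"), sep="\t", keep_default_na=False)


def load_assay_table(path=None) -> pd.DataFrame:
    """Assay TSV: labelled_species, sample_no, molecular_id, tlc, concentration, unit.

    Defaults to the packaged table of printed molecular/TLC/concentration
    results for the marketed samples.
    """
    src = path if path is not None else _data_path("table4_assays.tsv")
    df = pd.read_csv(src, sep="\t", dtype={"sample_no": str})
    return df


def classify_reported_id(
    molecular_id: str, labelled_species: str, taxonomy: pd.DataFrame
) -> MolecularCall:
    """Turn a reported identification string into a molecular verdict.

    Strings are species binomials, "<Genus> spp.", family names,
    "Unidentified" or "No sequence".  A taxon within the labelled species'
    genus is expected-side (authentic if the species matches, inconclusive
    at genus level); anything resolving outside it is a substitution.
    """
    tax = taxonomy.set_index("taxon")
    expected = tax.loc[labelled_species]
    sample_id = None  # filled by caller
    text = molecular_id.strip()
    if text.lower() == "no sequence":
        return MolecularCall("", labelled_species, "no_sequence", None, "no_sequence")
    if text.lower() == "unidentified":
        return MolecularCall("", labelled_species, "unidentified", None, "unidentified")
    name = text[:-5].strip() if text.endswith(" spp.") else text
    if name not in tax.index:
        raise KeyError(f"taxon {name!r} not in taxonomy table")
    row = tax.loc[name]
    if row["rank"] == "family":
        verdict = "inconclusive" if row.family == expected.family else "substitute"
        return MolecularCall("", labelled_species, verdict, name, "family")
    rank = row["rank"] if not text.endswith(" spp.") else "genus"
    taxon = row.genus if rank == "genus" else name
    if row.genus != expected.genus:
        return MolecularCall("", labelled_species, "substitute", taxon, rank)
    if rank == "species" and name == labelled_species:
        return MolecularCall("", labelled_species, "authentic", taxon, rank)
    if rank == "species":
        return MolecularCall("", labelled_species, "substitute", taxon, rank)
    return MolecularCall("", labelled_species, "inconclusive", taxon, rank)


def authenticate_assay_table(
    table: pd.DataFrame | None = None,
    specs: Mapping[str, ChemicalSpec] | None = None,
    taxonomy: pd.DataFrame | None = None,
) -> list[AuthenticationRecord]:
    """End-to-end authentication of an assay table of printed results."""
    table = load_assay_table() if table is None else table
    specs = load_chem_specs() if specs is None else specs
    taxonomy = load_market_taxonomy() if taxonomy is None else taxonomy
    records = []
    for row in table.itertuples():
        sample_id = f"{row.labelled_species}#{row.sample_no}"
        call = classify_reported_id(row.molecular_id, row.labelled_species, taxonomy)
        call.sample_id = sample_id
        conc = None if pd.isna(row.concentration) else float(row.concentration)
        assay = AssayResult(sample_id, row.tlc, conc, row.unit)
        records.append(authenticate_sample(call, assay, specs[row.labelled_species]))
    return records
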