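"""Domain model and I/O for urinary peptide analysis.

Peptides detected by CE-MS are reported as *modified sequence* strings in
which uppercase letters are unmodified residues, lowercase ``p`` is
hydroxyproline and lowercase ``m`` is methionine sulfoxide.  Each peptide
carries a sparse vector of per-participant signal amplitudes; an absent (or
zero) cell means the peptide was not detected in that participant, never
that it was detected with zero abundance.

The module also holds the cohort model (participants with age, eGFR and an
optional aetiology label), the reference precursor protein with its region
annotation, and the analysis configuration with the field-standard defaults
(detection frequency >= 100, variant-merge rho 0.5, strong-association rho
0.3, adjusted-p significance 0.05).
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

__all__ = [
    "InputError",
    "ConfigError",
    "Participant",
    "PeptideRecord",
    "ReferenceProtein",
    "AnalysisConfig",
    "parse_modified_sequence",
    "read_peptide_table",
    "write_peptide_table",
    "read_cohort_table",
    "write_cohort_table",
    "read_reference_fasta",
    "bundled_reference",
    "bundled_fragment_panel",
    "filter_by_frequency",
]

MODIFICATION_CODES = {"p": "hydroxyproline", "m": "methionine sulfoxide"}

#: default region annotation of the collagen alpha-1(I) precursor (1-based,
#: inclusive): signal peptide, N-propeptide, mature chain, C-propeptide.
COL1A1_REGIONS = (
    ("signal", 1, 22),
    ("N-propeptide", 23, 161),
    ("mature", 162, 1218),
    ("C-propeptide", 1219, 1464),
)


class InputError(ValueError):
    """Malformed or inconsistent input data (tables, sequences, FASTA)."""


class ConfigError(ValueError):
    """Invalid analysis configuration."""


def parse_modified_sequence(code: str) -> tuple[str, int, int]:
    """Parse a modified-sequence code into backbone and modification counts.

    Parameters
    ----------
    code
        Sequence over ``A-Z`` plus the lowercase modification letters
        ``p`` (hydroxyproline) and ``m`` (methionine sulfoxide).

    Returns
    -------
    tuple
        ``(unmod_seq, n_hyp, n_metox)`` where ``unmod_seq`` is the
        uppercased backbone, ``n_hyp`` the number of hydroxyprolines and
        ``n_metox`` the number of methionine sulfoxides.

    Raises
    ------
    InputError
        If the code is empty, non-alphabetic, or contains a lowercase
        character outside the modification alphabet.

    Examples
    --------
    >>> parse_modified_sequence("EpGSpGENGAPGQmGPR")
    ('EPGSPGENGAPGQMGPR', 2, 1)
    """
    if not code:
        raise InputError("empty modified-sequence code")
    n_hyp = n_metox = 0
    for i, ch in enumerate(code):
        if not ch.isalpha():
            raise InputError(
                f"non-alphabetic character {ch!r} at position {i + 1} in {code!r}")
        if ch.islower():
            if ch == "p":
                n_hyp += 1
            elif ch == "m":
                n_metox += 1
            else:
                raise InputError(
                    f"unrecognized modification code {ch!r} at position "
                    f"{i + 1} in {code!r} (allowed: {sorted(MODIFICATION_CODES)})")
    return code.upper(), n_hyp, n_metox


@dataclass(frozen=True)
class Participant:
    """One cohort member: id, age in years, eGFR in mL/min/1.73 m^2."""

    id: str
    age: float
    egfr: float
    aetiology: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("participant id must be non-empty")
        if not self.age > 0:
            raise InputError(f"participant {self.id}: age must be > 0")
        if not self.egfr > 0:
            raise InputError(f"participant {self.id}: eGFR must be > 0")


@dataclass
class PeptideRecord:
    """One detected peptide with its sparse per-participant intensities.

    ``intensities`` maps participant id to a strictly positive amplitude;
    participants in which the peptide was not detected are simply absent.
    ``frequency`` (detection frequency) is the number of participants with
    a detected signal.
    """

    modified_seq: str
    intensities: dict[str, float] = field(default_factory=dict)
    unmod_seq: str = field(init=False)
    n_hyp: int = field(init=False)
    n_metox: int = field(init=False)

    def __post_init__(self) -> None:
        self.unmod_seq, self.n_hyp, self.n_metox = parse_modified_sequence(
            self.modified_seq)
        bad = {k: v for k, v in self.intensities.items() if not v > 0}
        if bad:
            raise InputError(
                f"peptide {self.modified_seq}: non-positive intensities for "
                f"participants {sorted(bad)[:5]} (absent values must be "
                "omitted, not stored as zero)")

    @property
    def frequency(self) -> int:
        return len(self.intensities)

    @property
    def total_intensity(self) -> float:
        return float(sum(self.intensities.values()))


@dataclass(frozen=True)
class ReferenceProtein:
    """Reference precursor sequence with 1-based inclusive region annotation."""

    accession: str
    sequence: str
    regions: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        L = len(self.sequence)
        if L == 0:
            raise InputError("empty reference sequence")
        if self.sequence != self.sequence.upper():
            raise InputError("reference sequence must be uppercase")
        for name, start, stop in self.regions:
            if not (1 <= start <= stop <= L):
                raise InputError(
                    f"region {name} [{start}, {stop}] outside [1, {L}]")

    def __len__(self) -> int:
        return len(self.sequence)

    def region(self, name: str) -> tuple[int, int]:
        for n, a, b in self.regions:
            if n == name:
                return a, b
        raise KeyError(name)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable analysis parameters with their field-standard defaults.

    min_frequency
        Minimum detection frequency for a peptide to enter the analysis
        (kept iff ``frequency >= min_frequency``).
    rho_merge_threshold
        Minimum pairwise Spearman rho for hydroxyproline variants of one
        backbone to be aggregated into a single peptide.
    strong_rho
        |rho| above which a significant association is called strong.
    alpha
        Significance level on the Benjamini-Hochberg adjusted p-value.
    age_correction_onset, age_correction_slope
        Age-corrected eGFR adds ``slope`` mL/min/1.73 m^2 per year lived
        beyond ``onset`` years.
    age_bin_edges
        Interior edges of the 10-year age bins (<30, 30-40, ..., >70).
    n_per_bin
        Matched sub-cohort size per age bin.
    missing_policy
        How undetected intensities enter rank correlations: ``zero_fill``
        scores them as 0 (tied lowest rank), ``complete_case`` drops the
        participant for that computation.
    """

    min_frequency: int = 100
    rho_merge_threshold: float = 0.5
    strong_rho: float = 0.3
    alpha: float = 0.05
    age_correction_onset: float = 30.0
    age_correction_slope: float = 1.0
    age_bin_edges: tuple[float, ...] = (30.0, 40.0, 50.0, 60.0, 70.0)
    n_per_bin: int = 160
    missing_policy: Literal["zero_fill", "complete_case"] = "zero_fill"
    aggregate: Literal["sum", "mean"] = "sum"
    hotspot_min_count: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.strong_rho < 1:
            raise ConfigError("strong_rho must be in (0, 1)")
        if not 0 < self.rho_merge_threshold < 1:
            raise ConfigError("rho_merge_threshold must be in (0, 1)")
        if self.min_frequency < 2:
            raise ConfigError("min_frequency must be >= 2")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.missing_policy not in ("zero_fill", "complete_case"):
            raise ConfigError(f"unknown missing_policy {self.missing_policy!r}")
        if self.aggregate not in ("sum", "mean"):
            raise ConfigError(f"unknown aggregate {self.aggregate!r}")
        if list(self.age_bin_edges) != sorted(set(self.age_bin_edges)):
            raise ConfigError("age_bin_edges must be strictly increasing")
        if self.n_per_bin < 1:
            raise ConfigError("n_per_bin must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path}: expected a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"config {path}: unknown keys {sorted(unknown)}")
        if "age_bin_edges" in raw:
            raw["age_bin_edges"] = tuple(raw["age_bin_edges"])
        try:
            return cls(**raw)
        except TypeError as exc:  # pragma: no cover - defensive
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["age_bin_edges"] = list(self.age_bin_edges)
        return d

    def replace(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# table I/O


def _records_from_long(df: pd.DataFrame, where: str) -> list[PeptideRecord]:
    by_seq: dict[str, dict[str, float]] = {}
    for row in df.itertuples(index=False):
        seq, pid, val = str(row.modified_sequence), str(row.participant), row.intensity
        try:
            val = float(val)
        except (TypeError, ValueError):
            raise InputError(
                f"{where}: non-numeric intensity {val!r} for peptide {seq}, "
                f"participant {pid}") from None
        if val == 0 or pd.isna(val):
            continue
        cell = by_seq.setdefault(seq, {})
        if pid in cell:
            raise InputError(
                f"{where}: duplicate entry for peptide {seq}, participant {pid}")
        cell[pid] = val
    return [PeptideRecord(seq, vals) for seq, vals in by_seq.items()]


def read_peptide_table(path: str | Path, format: str = "wide") -> list[PeptideRecord]:
    """Read a peptide intensity table.

    ``wide``: one row per peptide, first column ``modified_sequence``,
    remaining columns one per participant; blank or 0 cells mean "not
    detected".  ``long``: columns ``modified_sequence``, ``participant``,
    ``intensity``.  Duplicate modified sequences are rejected.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    if format == "long":
        want = {"modified_sequence", "participant", "intensity"}
        if not want <= set(df.columns):
            raise InputError(f"{path}: long table needs columns {sorted(want)}")
        return _records_from_long(df, str(path))
    if format != "wide":
        raise InputError(f"unknown peptide-table format {format!r}")
    if "modified_sequence" not in df.columns:
        raise InputError(f"{path}: wide table needs a 'modified_sequence' column")
    dup = df["modified_sequence"][df["modified_sequence"].duplicated()]
    if not dup.empty:
        raise InputError(
            f"{path}: duplicate modified sequence(s): {sorted(set(dup))[:5]}")
    records = []
    pids = [c for c in df.columns if c != "modified_sequence"]
    for _, row in df.iterrows():
        intens: dict[str, float] = {}
        for pid in pids:
            raw = row[pid]
            if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw == "":
                continue
            try:
                val = float(raw)
            except (TypeError, ValueError):
                raise InputError(
                    f"{path}: non-numeric intensity {raw!r} in row "
                    f"{row['modified_sequence']}, column {pid}") from None
            if val != 0:
                intens[pid] = val
        records.append(PeptideRecord(str(row["modified_sequence"]), intens))
    return records


def write_peptide_table(records: Sequence[PeptideRecord], path: str | Path,
                        format: str = "wide",
                        participants: Iterable[str] | None = None) -> None:
    """Write peptide records in the same dialects ``read_peptide_table`` reads."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    if format == "long":
        rows = [(r.modified_seq, pid, val)
                for r in records for pid, val in sorted(r.intensities.items())]
        pd.DataFrame(rows, columns=["modified_sequence", "participant",
                                    "intensity"]).to_csv(path, sep=sep, index=False)
        return
    if format != "wide":
        raise InputError(f"unknown peptide-table format {format!r}")
    if participants is None:
        participants = sorted({p for r in records for p in r.intensities})
    cols = list(participants)
    data = {"modified_sequence": [r.modified_seq for r in records]}
    for pid in cols:
        data[pid] = [r.intensities.get(pid, None) for r in records]
    pd.DataFrame(data).to_csv(path, sep=sep, index=False)


def read_cohort_table(path: str | Path) -> list[Participant]:
    """Read a cohort TSV with columns id, age, egfr and optional aetiology."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"id": str})
    if not {"id", "age", "egfr"} <= set(df.columns):
        raise InputError(f"{path}: cohort table needs columns id, age, egfr")
    if df["id"].duplicated().any():
        dups = sorted(set(df["id"][df["id"].duplicated()]))
        raise InputError(f"{path}: duplicate participant id(s): {dups[:5]}")
    has_aet = "aetiology" in df.columns
    out = []
    for row in df.itertuples(index=False):
        aet = getattr(row, "aetiology", None) if has_aet else None
        if isinstance(aet, float) and pd.isna(aet):
            aet = None
        out.append(Participant(str(row.id), float(row.age), float(row.egfr), aet))
    return out


def write_cohort_table(cohort: Sequence[Participant], path: str | Path) -> None:
    pd.DataFrame(
        [(p.id, p.age, p.egfr, p.aetiology or "") for p in cohort],
        columns=["id", "age", "egfr", "aetiology"],
    ).to_csv(path, sep="\t", index=False)


def read_reference_fasta(path: str | Path,
                         regions: Sequence[tuple[str, int, int]] | None = None,
                         ) -> ReferenceProtein:
    """Read the first record of a FASTA file as the reference precursor.

    When the sequence is 1464 residues long the default collagen
    alpha-1(I) region annotation is attached unless ``regions`` overrides it.
    """
    try:
        rec = next(SeqIO.parse(str(path), "fasta"))
    except StopIteration:
        raise InputError(f"{path}: no FASTA records") from None
    seq = str(rec.seq).upper()
    if regions is None and len(seq) == 1464:
        regions = COL1A1_REGIONS
    return ReferenceProtein(rec.id, seq, tuple(regions or ()))


def bundled_reference() -> ReferenceProtein:
    """The bundled collagen alpha-1(I)-like precursor scaffold.

    A synthetic 1464-residue stand-in for the col1a1 precursor: it embeds
    the published urinary-fragment coordinates at their reported positions
    inside a Gly-X-Y helical region (residues 179-1192) but is not the
    natural sequence.  Region annotation follows the precursor layout
    (signal 1-22, N-propeptide 23-161, mature 162-1218, C-propeptide
    1219-1464).
    """
    ref = importlib.resources.files("colpep.data") / "col1a1_synthetic.fasta"
    with importlib.resources.as_file(ref) as p:
        return read_reference_fasta(p, regions=COL1A1_REGIONS)


def bundled_fragment_panel() -> pd.DataFrame:
    """Published top-10 fragment panels (long format).

    One row per (fragment, covariate) pair with reported precursor
    coordinates and Spearman rho / BH-adjusted p against eGFR, age,
    age-corrected eGFR, and age within the eGFR-matched sub-cohort.
    """
    ref = importlib.resources.files("colpep.data") / "reference_fragments.tsv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def filter_by_frequency(records: Sequence[PeptideRecord],
                        min_frequency: int) -> list[PeptideRecord]:
    """Keep peptides detected in at least ``min_frequency`` participants."""
    if min_frequency < 1:
        raise InputError("min_frequency must be >= 1")
    return [r for r in records if r.frequency >= min_frequency]
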