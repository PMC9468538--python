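"""Data model and tabular I/O for the durum wheat MTA meta-analysis.

All interchange tables are tab-separated text with a fixed header, ``#`` comment
lines and ``NA`` for missing values.  The tetraploid durum genome has 14
chromosomes, named ``1A`` .. ``7B``; the trailing letter is the (sub)genome.

The module defines one dataclass per table row plus the genetic-map containers,
readers and writers for each table, and the descriptive database summaries
(MTA counts per chromosome and genome, confidence-interval and PVE histograms).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "DURUM_CHROMOSOMES",
    "Study",
    "TraitDictionary",
    "MTARecord",
    "GeneticMap",
    "LDDecayTable",
    "AnchorTable",
    "ValidationError",
    "ParseError",
    "normalize_chromosome",
    "genome_of",
    "load_studies",
    "write_studies",
    "load_trait_dictionary",
    "count_trait_entries",
    "load_mta",
    "write_mta",
    "load_genetic_map",
    "write_genetic_map",
    "load_ld_decay",
    "write_ld_decay",
    "load_anchor_table",
    "write_anchor_table",
    "summarize_database",
    "packaged_fixture",
]

DURUM_CHROMOSOMES: tuple[str, ...] = tuple(
    f"{n}{g}" for n in range(1, 8) for g in ("A", "B")
)


class ValidationError(ValueError):
    """A table row violates a model invariant."""


class ParseError(ValueError):
    """A table cell cannot be parsed; the message names the offending line."""


def normalize_chromosome(name: str) -> str:
    """Normalize a chromosome label to the canonical ``1A`` .. ``7B`` form.

    Raises :class:`ValidationError` for anything outside the 14 durum names.
    """
    chrom = str(name).strip().upper()
    if chrom.startswith("CHR"):
        chrom = chrom[3:]
    if chrom not in DURUM_CHROMOSOMES:
        raise ValidationError(f"not a durum wheat chromosome: {name!r}")
    return chrom


def genome_of(chromosome: str) -> str:
    """Return the subgenome letter (``A`` or ``B``) of a chromosome name."""
    return normalize_chromosome(chromosome)[-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Study:
    """One GWAS study contributing MTAs: association panel and declared counts."""

    study_id: str
    panel: str
    size: int
    trait_codes: frozenset[str]
    n_mta_declared: int

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValidationError(f"study {self.study_id}: size must be >= 1")
        if self.n_mta_declared < 0:
            raise ValidationError(f"study {self.study_id}: negative n_mta")
        if not self.trait_codes:
            raise ValidationError(f"study {self.study_id}: empty trait set")


@dataclass(frozen=True)
class TraitDictionary:
    """Lookup of trait codes to descriptions.

    Codes may legitimately repeat with distinct descriptions (e.g. GPC is both
    "Grain protein content" and "Protein content" in different source studies),
    so entries are an ordered list of pairs, not a mapping.
    """

    entries: tuple[tuple[str, str], ...]

    def __len__(self) -> int:
        return len(self.entries)

    def descriptions(self, code: str) -> list[str]:
        return [d for c, d in self.entries if c == code]


@dataclass(frozen=True)
class MTARecord:
    """One marker-trait association in source-map coordinates.

    ``ci_cM`` is the full width of the 95% confidence interval; ``pve`` the
    proportion of phenotypic variance explained, stored as a fraction in
    [0, 1].  Both may be missing (``None``); missingness is preserved, never
    silently replaced by zero.
    """

    mta_id: str
    study_id: str
    trait_code: str
    chromosome: str
    position_cM: float
    ci_cM: float | None = None
    pve: float | None = None
    marker_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        if self.position_cM < 0:
            raise ValidationError(f"{self.mta_id}: negative position")
        if self.ci_cM is not None and self.ci_cM <= 0:
            raise ValidationError(f"{self.mta_id}: CI width must be positive")
        if self.pve is not None and not (0.0 <= self.pve <= 1.0):
            raise ValidationError(f"{self.mta_id}: PVE outside [0, 1]")


@dataclass(frozen=True)
class GeneticMap:
    """A genetic map: marker -> (chromosome, cM) plus chromosome lengths."""

    name: str
    positions: Mapping[str, tuple[str, float]]
    chrom_lengths_cM: Mapping[str, float]

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_lengths_cM.items():
            if length <= 0:
                raise ValidationError(f"{self.name}: non-positive length on {chrom}")
        for marker, (chrom, cm) in self.positions.items():
            length = self.chrom_lengths_cM.get(chrom)
            if length is not None and cm > length + 1e-9:
                raise ValidationError(
                    f"{self.name}: marker {marker} at {cm} cM beyond {chrom} "
                    f"length {length}"
                )

    def markers_on(self, chromosome: str) -> list[tuple[str, float]]:
        """Markers on one chromosome, sorted by position."""
        chrom = normalize_chromosome(chromosome)
        out = [(m, cm) for m, (c, cm) in self.positions.items() if c == chrom]
        out.sort(key=lambda t: (t[1], t[0]))
        return out


@dataclass(frozen=True)
class LDDecayTable:
    """Per-chromosome LD-decay distance (cM), the CI surrogate for CI-less MTAs."""

    decay_cM: Mapping[str, float]

    def __post_init__(self) -> None:
        for chrom, d in self.decay_cM.items():
            if d <= 0:
                raise ValidationError(f"LD decay on {chrom} must be positive")

    def __getitem__(self, chromosome: str) -> float:
        return self.decay_cM[normalize_chromosome(chromosome)]

    def __contains__(self, chromosome: str) -> bool:
        return normalize_chromosome(chromosome) in self.decay_cM


@dataclass(frozen=True)
class AnchorTable:
    """Genetic (cM) to physical (Mb) anchor points on one reference assembly."""

    reference_name: str
    anchors: Mapping[str, tuple[tuple[float, float], ...]]

    def __post_init__(self) -> None:
        for chrom, pts in self.anchors.items():
            if len(pts) < 2:
                raise ValidationError(
                    f"{self.reference_name}/{chrom}: need >= 2 anchors"
                )
            cms = [cm for cm, _ in pts]
            if any(b <= a for a, b in zip(cms, cms[1:])):
                raise ValidationError(
                    f"{self.reference_name}/{chrom}: anchor cM not strictly increasing"
                )
            if any(mb <= 0 for _, mb in pts):
                raise ValidationError(
                    f"{self.reference_name}/{chrom}: non-positive Mb anchor"
                )


# ---------------------------------------------------------------------------
# TSV primitives
# ---------------------------------------------------------------------------

_NA = "NA"


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}; header was {list(df.columns)}")
    return df


def _cell(row: pd.Series, col: str, line: int, path: Path, kind=float):
    raw = row[col].strip()
    if raw == "" or raw == _NA:
        return None
    try:
        return kind(raw)
    except ValueError as exc:
        raise ParseError(f"{path}:{line}: bad {col} value {raw!r}") from exc


def _data_line_numbers(path: Path, n: int) -> list[int]:
    """1-based file line number of each data row (comments/header skipped)."""
    numbers = []
    with open(path) as fh:
        seen_header = False
        for i, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            if not seen_header:
                seen_header = True
                continue
            numbers.append(i)
    return numbers[:n]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

STUDY_COLUMNS = ["study_id", "panel", "size", "n_mta", "traits"]
MTA_COLUMNS = [
    "mta_id",
    "study_id",
    "trait_code",
    "chromosome",
    "position_cM",
    "ci_cM",
    "pve",
    "marker_id",
]
MAP_COLUMNS = ["marker", "chromosome", "position_cM"]
LD_COLUMNS = ["chromosome", "decay_cM"]
ANCHOR_COLUMNS = ["chromosome", "marker", "position_cM", "position_Mb"]


def load_studies(path: str | Path) -> list[Study]:
    """Read a study-summary table (one row per GWAS study)."""
    path = Path(path)
    df = _read_tsv(path, STUDY_COLUMNS)
    lines = _data_line_numbers(path, len(df))
    studies: list[Study] = []
    seen: set[str] = set()
    for (idx, row), line in zip(df.iterrows(), lines):
        size = _cell(row, "size", line, path, int)
        n_mta = _cell(row, "n_mta", line, path, int)
        if size is None or n_mta is None:
            raise ParseError(f"{path}:{line}: size and n_mta are required")
        sid = row["study_id"].strip()
        if sid in seen:
            raise ValidationError(f"{path}:{line}: duplicate study_id {sid!r}")
        seen.add(sid)
        codes = frozenset(
            c.strip() for c in row["traits"].split(",") if c.strip()
        )
        studies.append(
            Study(
                study_id=sid,
                panel=row["panel"].strip(),
                size=size,
                trait_codes=codes,
                n_mta_declared=n_mta,
            )
        )
    return studies


def write_studies(studies: Iterable[Study], path: str | Path) -> None:
    rows = [
        {
            "study_id": s.study_id,
            "panel": s.panel,
            "size": s.size,
            "n_mta": s.n_mta_declared,
            "traits": ",".join(sorted(s.trait_codes)),
        }
        for s in studies
    ]
    pd.DataFrame(rows, columns=STUDY_COLUMNS).to_csv(path, sep="\t", index=False)


def load_trait_dictionary(path: str | Path) -> TraitDictionary:
    df = _read_tsv(path, ["code", "description"])
    entries = tuple(
        (row["code"].strip(), row["description"].strip()) for _, row in df.iterrows()
    )
    return TraitDictionary(entries=entries)


def count_trait_entries(dictionary: TraitDictionary) -> int:
    """Number of (code, description) entries, duplicates counted separately."""
    return len(dictionary)


def load_mta(path: str | Path, *, pve_as_percent: bool = False) -> list[MTARecord]:
    """Read an MTA table.

    ``pve_as_percent`` declares that the source table reports PVE on the 0-100
    scale; values are stored internally as fractions either way.  Missing CI
    and PVE cells (``NA``) stay missing.
    """
    path = Path(path)
    df = _read_tsv(path, MTA_COLUMNS)
    lines = _data_line_numbers(path, len(df))
    records: list[MTARecord] = []
    for (idx, row), line in zip(df.iterrows(), lines):
        pos = _cell(row, "position_cM", line, path)
        if pos is None:
            raise ParseError(f"{path}:{line}: position_cM is required")
        pve = _cell(row, "pve", line, path)
        if pve is not None and pve_as_percent:
            pve = pve / 100.0
        marker = row["marker_id"].strip()
        try:
            records.append(
                MTARecord(
                    mta_id=row["mta_id"].strip(),
                    study_id=row["study_id"].strip(),
                    trait_code=row["trait_code"].strip(),
                    chromosome=row["chromosome"],
                    position_cM=pos,
                    ci_cM=_cell(row, "ci_cM", line, path),
                    pve=pve,
                    marker_id=None if marker in ("", _NA) else marker,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}:{line}: {exc}") from exc
    return records


def write_mta(records: Iterable[MTARecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "mta_id": r.mta_id,
                "study_id": r.study_id,
                "trait_code": r.trait_code,
                "chromosome": r.chromosome,
                "position_cM": f"{r.position_cM:.6g}",
                "ci_cM": _NA if r.ci_cM is None else f"{r.ci_cM:.6g}",
                "pve": _NA if r.pve is None else f"{r.pve:.6g}",
                "marker_id": _NA if r.marker_id is None else r.marker_id,
            }
        )
    pd.DataFrame(rows, columns=MTA_COLUMNS).to_csv(path, sep="\t", index=False)


def load_genetic_map(path: str | Path, name: str | None = None) -> GeneticMap:
    """Read a genetic map.  Chromosome lengths come from ``# length <chrom> <cM>``
    header comments when present, else from the maximum marker position."""
    path = Path(path)
    lengths: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("# length"):
                _, _, chrom, cm = line.split()
                lengths[normalize_chromosome(chrom)] = float(cm)
    df = _read_tsv(path, MAP_COLUMNS)
    positions: dict[str, tuple[str, float]] = {}
    for _, row in df.iterrows():
        chrom = normalize_chromosome(row["chromosome"])
        positions[row["marker"].strip()] = (chrom, float(row["position_cM"]))
    if not lengths:
        for chrom, cm in positions.values():
            lengths[chrom] = max(lengths.get(chrom, 0.0), cm)
    return GeneticMap(
        name=name or Path(path).stem, positions=positions, chrom_lengths_cM=lengths
    )


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(gmap.chrom_lengths_cM):
            fh.write(f"# length {chrom} {gmap.chrom_lengths_cM[chrom]:.6g}\n")
        fh.write("\t".join(MAP_COLUMNS) + "\n")
        for marker in sorted(
            gmap.positions, key=lambda m: (gmap.positions[m][0], gmap.positions[m][1], m)
        ):
            chrom, cm = gmap.positions[marker]
            fh.write(f"{marker}\t{chrom}\t{cm:.6g}\n")


def load_ld_decay(path: str | Path) -> LDDecayTable:
    df = _read_tsv(path, LD_COLUMNS)
    decay = {
        normalize_chromosome(row["chromosome"]): float(row["decay_cM"])
        for _, row in df.iterrows()
    }
    return LDDecayTable(decay_cM=decay)


def write_ld_decay(table: LDDecayTable, path: str | Path) -> None:
    rows = [
        {"chromosome": c, "decay_cM": f"{d:.6g}"}
        for c, d in sorted(table.decay_cM.items())
    ]
    pd.DataFrame(rows, columns=LD_COLUMNS).to_csv(path, sep="\t", index=False)


def load_anchor_table(path: str | Path, reference_name: str) -> AnchorTable:
    df = _read_tsv(path, ANCHOR_COLUMNS)
    anchors: dict[str, list[tuple[float, float]]] = {}
    for _, row in df.iterrows():
        chrom = normalize_chromosome(row["chromosome"])
        anchors.setdefault(chrom, []).append(
            (float(row["position_cM"]), float(row["position_Mb"]))
        )
    fixed = {c: tuple(sorted(pts)) for c, pts in anchors.items()}
    return AnchorTable(reference_name=reference_name, anchors=fixed)


def write_anchor_table(table: AnchorTable, path: str | Path) -> None:
    rows = []
    for chrom in sorted(table.anchors):
        for i, (cm, mb) in enumerate(table.anchors[chrom]):
            rows.append(
                {
                    "chromosome": chrom,
                    "marker": f"anchor_{chrom}_{i:02d}",
                    "position_cM": f"{cm:.6g}",
                    "position_Mb": f"{mb:.6g}",
                }
            )
    pd.DataFrame(rows, columns=ANCHOR_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# descriptive summaries
# ---------------------------------------------------------------------------


def summarize_database(
    mta: Sequence[MTARecord], studies: Sequence[Study] | None = None
) -> dict:
    """Descriptive summary of an MTA database.

    Returns per-chromosome counts, the A/B genome split, per-trait counts, the
    histogram of original CI widths (<=5, <=10, >10 cM, missing) and of PVE
    (<0.1, <0.2, >=0.2, missing), plus study totals when studies are given.
    An empty database yields empty (all-zero) summaries.
    """
    per_chrom = {c: 0 for c in DURUM_CHROMOSOMES}
    per_trait: dict[str, int] = {}
    ci_hist = {"le_5": 0, "le_10": 0, "gt_10": 0, "missing": 0}
    pve_hist = {"lt_0.1": 0, "lt_0.2": 0, "ge_0.2": 0, "missing": 0}
    ci_values: list[float] = []
    for r in mta:
        per_chrom[r.chromosome] += 1
        per_trait[r.trait_code] = per_trait.get(r.trait_code, 0) + 1
        if r.ci_cM is None:
            ci_hist["missing"] += 1
        else:
            ci_values.append(r.ci_cM)
            if r.ci_cM <= 5:
                ci_hist["le_5"] += 1
                ci_hist["le_10"] += 1
            elif r.ci_cM <= 10:
                ci_hist["le_10"] += 1
            else:
                ci_hist["gt_10"] += 1
        if r.pve is None:
            pve_hist["missing"] += 1
        elif r.pve < 0.1:
            pve_hist["lt_0.1"] += 1
            pve_hist["lt_0.2"] += 1
        elif r.pve < 0.2:
            pve_hist["lt_0.2"] += 1
        else:
            pve_hist["ge_0.2"] += 1

    total = len(mta)
    n_a = sum(n for c, n in per_chrom.items() if c.endswith("A"))
    n_b = total - n_a
    summary = {
        "n_mta": total,
        "mta_per_chromosome": per_chrom,
        "mean_mta_per_chromosome": (total / len(DURUM_CHROMOSOMES)) if total else 0.0,
        "genome_share_pct": {
            "A": 100.0 * n_a / total if total else 0.0,
            "B": 100.0 * n_b / total if total else 0.0,
        },
        "mta_per_trait": dict(sorted(per_trait.items())),
        "ci_histogram": ci_hist,
        "ci_mean_cM": (sum(ci_values) / len(ci_values)) if ci_values else None,
        "pve_histogram": pve_hist,
    }
    if studies is not None:
        summary["n_studies"] = len(studies)
        summary["total_genotypes"] = sum(s.size for s in studies)
        summary["n_mta_declared"] = sum(s.n_mta_declared for s in studies)
    return summary


def summary_to_json(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


def summary_to_tsv(summary: dict, path: str | Path) -> None:
    """Flat key/value twin of the JSON summary (nested keys dot-joined)."""
    rows: list[tuple[str, object]] = []

    def walk(prefix: str, obj) -> None:
        if isinstance(obj, dict):
            for key, value in obj.items():
                walk(f"{prefix}.{key}" if prefix else str(key), value)
        else:
            rows.append((prefix, obj))

    walk("", summary)
    pd.DataFrame(rows, columns=["key", "value"]).to_csv(path, sep="\t", index=False)


def packaged_fixture(name: str) -> Path:
    """Path to one of the tables shipped with the package (printed-table data)."""
    path = Path(__file__).parent / "data" / name
    if not path.exists():
        raise FileNotFoundError(path)
    return path
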