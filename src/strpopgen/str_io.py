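"""Input/output and validation for STR population datasets.

Two data modes are supported, mirroring how worldwide forensic STR data are
published:

* **frequency mode** — per (population, locus) allele-frequency tables with
  the number of gene copies they summarise (the typical forensic-journal
  export);
* **genotype mode** — diploid repeat-number calls per individual (GenePop
  interchange or a native long-format CSV).

Allele labels are repeat counts in decimal units; imperfect alleles such as
``9.3`` (9 full repeats plus a partial motif) are carried as their literal
decimal value in all repeat-number arithmetic.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "ValidationError",
    "FrequencyTable",
    "GenotypeTable",
    "PopulationMetadata",
    "HierarchyConfig",
    "GenepopResult",
    "read_frequency_table",
    "write_frequency_table",
    "read_genotypes_genepop",
    "write_genotypes_genepop",
    "read_genotypes_csv",
    "write_genotypes_csv",
    "read_metadata",
    "write_metadata",
    "frequencies_from_genotypes",
    "drop_loci",
    "format_allele",
    "COMPLEX_LOCI",
]

#: Loci with imperfect-repeat structure that a robustness run may exclude.
COMPLEX_LOCI = ("FGA", "D21S11", "TH01")


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Parsed data violate a dataset invariant."""


def format_allele(a: float) -> str:
    """Format a repeat-unit allele label, e.g. ``9.0 -> '9'``, ``9.3 -> '9.3'``."""
    if float(a) == int(a):
        return str(int(a))
    return f"{a:g}"


def _parse_allele(text: str, where: str) -> float:
    try:
        v = float(text)
    except ValueError:
        raise ParseError(f"{where}: allele label {text!r} is not a decimal number")
    if v < 0 or not math.isfinite(v):
        raise ParseError(f"{where}: allele label {text!r} must be nonnegative and finite")
    return v


# ---------------------------------------------------------------------------
# Frequency mode
# ---------------------------------------------------------------------------


@dataclass
class FrequencyTable:
    """Allele-frequency dataset: per (population, locus) a frequency map.

    Parameters
    ----------
    populations, loci
        Ordered ids.  Every (population, locus) pair must have an entry.
    cells
        Mapping ``(population, locus) -> (freqs, n_copies)`` where ``freqs``
        maps the allele repeat value (float) to its frequency and
        ``n_copies`` is the number of gene copies the frequencies summarise
        (2 x sampled individuals).
    """

    populations: list[str]
    loci: list[str]
    cells: dict[tuple[str, str], tuple[dict[float, float], int]]

    def validate(self, tolerance: float = 1e-3) -> "FrequencyTable":
        for pop in self.populations:
            for locus in self.loci:
                key = (pop, locus)
                if key not in self.cells:
                    raise ValidationError(f"missing cell for population {pop!r}, locus {locus!r}")
                freqs, n = self.cells[key]
                if not freqs:
                    raise ValidationError(f"({pop}, {locus}): empty allele map")
                if int(n) != n or n < 2:
                    raise ValidationError(f"({pop}, {locus}): n_copies {n} must be an integer >= 2")
                total = 0.0
                for a, f in freqs.items():
                    if a < 0:
                        raise ValidationError(f"({pop}, {locus}): negative allele label {a}")
                    if not 0.0 < f <= 1.0:
                        raise ValidationError(f"({pop}, {locus}): frequency {f} outside (0, 1]")
                    total += f
                if abs(total - 1.0) > tolerance:
                    raise ValidationError(
                        f"({pop}, {locus}): frequencies sum to {total:.6f}, "
                        f"deviating from 1 by more than {tolerance}"
                    )
        return self

    def cell(self, population: str, locus: str) -> tuple[dict[float, float], int]:
        return self.cells[(population, locus)]

    def allele_counts(self, population: str, locus: str) -> tuple[np.ndarray, np.ndarray]:
        """Reconstruct integer copy counts for a cell.

        Counts are ``round(frequency * n_copies)`` reconciled to sum exactly
        to ``n_copies`` by the largest-remainder rule, so frequencies that
        were produced from integer counts are recovered exactly.
        """
        freqs, n = self.cells[(population, locus)]
        values = np.array(sorted(freqs), dtype=float)
        raw = np.array([freqs[v] * n for v in values])
        counts = np.floor(raw).astype(int)
        remainder = int(round(n - counts.sum()))
        if remainder > 0:
            order = np.argsort(-(raw - np.floor(raw)), kind="stable")
            counts[order[:remainder]] += 1
        elif remainder < 0:  # defensive; frequencies summing to <= 1 cannot overfill
            order = np.argsort(raw - np.floor(raw), kind="stable")
            counts[order[: -remainder]] -= 1
        keep = counts > 0
        return values[keep], counts[keep]


def read_frequency_table(path, tolerance: float = 1e-3) -> FrequencyTable:
    """Read a long-format allele-frequency file (CSV or TSV).

    Required header columns: ``population, locus, allele, frequency,
    n_copies``.  Rows for the same (population, locus) are merged; alleles
    with frequency 0 are dropped; a duplicate allele within a cell, or a
    frequency sum deviating from 1 by more than ``tolerance``, raises
    :class:`ValidationError`.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    reader = csv.DictReader(io.StringIO(text), delimiter=delim)
    required = {"population", "locus", "allele", "frequency", "n_copies"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        raise ParseError(f"{path}: header must contain columns {sorted(required)}")

    cells: dict[tuple[str, str], tuple[dict[float, float], int]] = {}
    populations: list[str] = []
    loci: list[str] = []
    for lineno, row in enumerate(reader, start=2):
        where = f"{path}:{lineno}"
        pop = (row["population"] or "").strip()
        locus = (row["locus"] or "").strip()
        if not pop or not locus:
            raise ParseError(f"{where}: empty population or locus field")
        allele = _parse_allele((row["allele"] or "").strip(), where)
        try:
            freq = float(row["frequency"])
            n = int(row["n_copies"])
        except (TypeError, ValueError):
            raise ParseError(f"{where}: malformed frequency or n_copies")
        if pop not in populations:
            populations.append(pop)
        if locus not in loci:
            loci.append(locus)
        key = (pop, locus)
        if key not in cells:
            cells[key] = ({}, n)
        freqs, n0 = cells[key]
        if n != n0:
            raise ValidationError(f"{where}: inconsistent n_copies for ({pop}, {locus})")
        if freq == 0.0:
            continue
        if allele in freqs:
            raise ValidationError(f"{where}: duplicate allele {format_allele(allele)} in ({pop}, {locus})")
        freqs[allele] = freq

    table = FrequencyTable(populations, loci, cells)
    return table.validate(tolerance)


def write_frequency_table(table: FrequencyTable, path, sep: str = "\t") -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter=sep)
        w.writerow(["population", "locus", "allele", "frequency", "n_copies"])
        for pop in table.populations:
            for locus in table.loci:
                freqs, n = table.cells[(pop, locus)]
                for a in sorted(freqs):
                    w.writerow([pop, locus, format_allele(a), f"{freqs[a]:.6f}", n])


# ---------------------------------------------------------------------------
# Genotype mode
# ---------------------------------------------------------------------------


@dataclass
class GenotypeTable:
    """Diploid repeat-number calls, individuals x loci x 2.

    ``calls[i, l]`` is the unordered allele pair of individual ``i`` at locus
    ``l`` in repeat units (floats; imperfect alleles keep their decimal
    value).  The validated object contains no missing calls.
    """

    individuals: list[str]
    population_of: list[str]
    loci: list[str]
    calls: np.ndarray  # (n_individuals, n_loci, 2) float

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.individuals), len(self.loci), 2):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci x 2"
            )
        if len(self.population_of) != len(self.individuals):
            raise ValidationError("population_of must parallel individuals")
        if not np.isfinite(self.calls).all() or (self.calls < 0).any():
            raise ValidationError("all calls must be finite nonnegative repeat values")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.population_of:
            seen.setdefault(p)
        return list(seen)

    def individuals_in(self, population: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.population_of, dtype=object) == population)

    def copies(self, population: str, locus: str) -> np.ndarray:
        """All allele copies (2 per individual) for one population x locus."""
        li = self.loci.index(locus)
        idx = self.individuals_in(population)
        return self.calls[idx, li, :].ravel()

    def allele_counts(self, population: str, locus: str) -> tuple[np.ndarray, np.ndarray]:
        values, counts = np.unique(self.copies(population, locus), return_counts=True)
        return values, counts

    def subset_loci(self, loci: Sequence[str]) -> "GenotypeTable":
        idx = [self.loci.index(l) for l in loci]
        return GenotypeTable(
            list(self.individuals), list(self.population_of), list(loci), self.calls[:, idx, :]
        )


def frequencies_from_genotypes(g: GenotypeTable) -> FrequencyTable:
    """Convert genotype calls to per-population allele frequencies.

    Per (population, locus): frequency of allele a = copies of a / (2 x
    individuals); ``n_copies`` = 2 x individuals.  The output satisfies the
    frequency-table invariants exactly (sums equal 1 up to float rounding).
    """
    pops = g.populations
    cells: dict[tuple[str, str], tuple[dict[float, float], int]] = {}
    for pop in pops:
        idx = g.individuals_in(pop)
        n = 2 * len(idx)
        for li, locus in enumerate(g.loci):
            copies = g.calls[idx, li, :].ravel()
            values, counts = np.unique(copies, return_counts=True)
            cells[(pop, locus)] = ({float(v): c / n for v, c in zip(values, counts)}, n)
    return FrequencyTable(pops, list(g.loci), cells).validate()


def drop_loci(data, loci: Iterable[str] = COMPLEX_LOCI):
    """Remove the listed loci from a frequency or genotype table.

    Default list: the loci with complex/imperfect repeat structure (FGA,
    D21S11, TH01), supporting the 10-locus robustness run.
    """
    drop = {l for l in loci}
    if isinstance(data, GenotypeTable):
        keep = [l for l in data.loci if l not in drop]
        if not keep:
            raise ValidationError("dropping these loci would leave no data")
        return data.subset_loci(keep)
    keep = [l for l in data.loci if l not in drop]
    if not keep:
        raise ValidationError("dropping these loci would leave no data")
    cells = {
        (p, l): data.cells[(p, l)] for p in data.populations for l in keep
    }
    return FrequencyTable(list(data.populations), keep, cells)


# ---------------------------------------------------------------------------
# GenePop interchange
# ---------------------------------------------------------------------------


@dataclass
class GenepopResult:
    table: GenotypeTable
    populations: list[str]
    n_dropped: int
    dropped_ids: list[str] = field(default_factory=list)


def _decode_genepop_field(token: str, where: str) -> tuple[float, float]:
    if len(token) % 2 != 0 or len(token) < 4:
        raise ParseError(f"{where}: allele code {token!r} has odd or short length")
    w = len(token) // 2
    if w not in (2, 3, 4):
        raise ParseError(f"{where}: unsupported allele code width {w}")
    out = []
    for part in (token[:w], token[w:]):
        try:
            code = int(part)
        except ValueError:
            raise ParseError(f"{where}: non-numeric allele code {part!r}")
        # 2/3-digit codes are repeat counts; the extended 4-digit code is
        # repeat x 10 so that microvariants like 9.3 (-> 0093) survive.
        out.append(code / 10.0 if w == 4 else float(code))
    return out[0], out[1]


def read_genotypes_genepop(path) -> GenepopResult:
    """Read a GenePop file (2-, 3- or extended 4-digit allele codes).

    Populations are delimited by ``POP`` lines and named after their first
    individual's label.  Individuals with any missing call (code 0) at the
    analysed loci are dropped and counted in the returned report.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ParseError(f"{path}: empty file")
    body = lines[1:]  # first line is the title
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().upper() != "POP":
        ln = body[i].strip()
        if ln:
            loci.extend(x.strip() for x in ln.split(",") if x.strip())
        i += 1
    if i == len(body):
        raise ParseError(f"{path}: no POP block found")
    if not loci:
        raise ParseError(f"{path}: no locus names before the first POP line")

    individuals: list[str] = []
    population_of: list[str] = []
    rows: list[list[tuple[float, float]]] = []
    dropped: list[str] = []
    pop_order: list[str] = []
    current_pop: str | None = None
    for lineno in range(i, len(body)):
        ln = body[lineno].strip()
        if not ln:
            continue
        if ln.upper() == "POP":
            current_pop = None
            continue
        where = f"{path}:{lineno + 2}"
        if "," not in ln:
            raise ParseError(f"{where}: individual line lacks the ',' separator")
        ind_id, geno = ln.split(",", 1)
        ind_id = ind_id.strip()
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise ParseError(f"{where}: expected {len(loci)} genotype fields, found {len(tokens)}")
        if current_pop is None:
            current_pop = ind_id
            pop_order.append(current_pop)
        pairs = [_decode_genepop_field(t, where) for t in tokens]
        if any(a == 0.0 or b == 0.0 for a, b in pairs):
            dropped.append(ind_id)
            continue
        individuals.append(ind_id)
        population_of.append(current_pop)
        rows.append(pairs)

    if not individuals:
        raise ParseError(f"{path}: zero individuals retained after missing-data filter")
    calls = np.array(rows, dtype=float)
    table = GenotypeTable(individuals, population_of, loci, calls)
    return GenepopResult(table, pop_order, len(dropped), dropped)


def write_genotypes_genepop(g: GenotypeTable, path, title: str = "strpopgen export") -> None:
    """Write GenePop; uses the extended 4-digit (repeat x 10) code when any
    allele is a decimal microvariant, 3-digit codes otherwise."""
    extended = bool((g.calls != np.round(g.calls)).any())
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(title + "\n")
        for locus in g.loci:
            fh.write(locus + "\n")
        last_pop = None
        for i, (ind, pop) in enumerate(zip(g.individuals, g.population_of)):
            if pop != last_pop:
                fh.write("POP\n")
                last_pop = pop
            fields = []
            for li in range(len(g.loci)):
                a, b = g.calls[i, li]
                if extended:
                    fields.append(f"{int(round(a * 10)):04d}{int(round(b * 10)):04d}")
                else:
                    fields.append(f"{int(round(a)):03d}{int(round(b)):03d}")
            fh.write(f"{ind} ,  " + " ".join(fields) + "\n")


def read_genotypes_csv(path) -> GenotypeTable:
    """Read the native long-format genotype CSV
    (individual, population, locus, allele1, allele2)."""
    df = pd.read_csv(path, dtype={"individual": str, "population": str, "locus": str})
    required = {"individual", "population", "locus", "allele1", "allele2"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: header must contain columns {sorted(required)}")
    loci = list(dict.fromkeys(df["locus"]))
    inds = list(dict.fromkeys(df["individual"]))
    pop_of = dict(zip(df["individual"], df["population"]))
    wide = df.set_index(["individual", "locus"])
    calls = np.empty((len(inds), len(loci), 2), dtype=float)
    try:
        for ii, ind in enumerate(inds):
            for li, locus in enumerate(loci):
                row = wide.loc[(ind, locus)]
                calls[ii, li] = (float(row["allele1"]), float(row["allele2"]))
    except KeyError as e:
        raise ValidationError(f"{path}: individual missing a call at {e.args[0]}")
    return GenotypeTable(inds, [pop_of[i] for i in inds], loci, calls)


def write_genotypes_csv(g: GenotypeTable, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["individual", "population", "locus", "allele1", "allele2"])
        for i, (ind, pop) in enumerate(zip(g.individuals, g.population_of)):
            for li, locus in enumerate(g.loci):
                a, b = g.calls[i, li]
                w.writerow([ind, pop, locus, format_allele(a), format_allele(b)])


# ---------------------------------------------------------------------------
# Metadata and hierarchy
# ---------------------------------------------------------------------------


@dataclass
class PopulationMetadata:
    """Per-population geography: coordinates, geographic group (e.g. SAF,
    EUR, EAS), routing region for waypoint lookup, and the curator's
    well-defined flag."""

    table: pd.DataFrame  # index: population id; columns name, group, lat, lon, region, well_defined

    def __post_init__(self) -> None:
        required = {"name", "group", "lat", "lon", "region", "well_defined"}
        if not required.issubset(self.table.columns):
            raise ValidationError(f"metadata must have columns {sorted(required)}")
        lat, lon = self.table["lat"], self.table["lon"]
        if ((lat < -90) | (lat > 90)).any() or ((lon < -180) | (lon > 180)).any():
            raise ValidationError("latitude must be in [-90, 90] and longitude in [-180, 180]")
        for col in ("group", "region"):
            if (self.table[col].astype(str).str.len() == 0).any():
                raise ValidationError(f"{col} labels must be non-empty")

    @property
    def populations(self) -> list[str]:
        return list(self.table.index)

    def coords(self, population: str) -> tuple[float, float]:
        row = self.table.loc[population]
        return float(row["lat"]), float(row["lon"])

    def group(self, population: str) -> str:
        return str(self.table.loc[population, "group"])

    def region(self, population: str) -> str:
        return str(self.table.loc[population, "region"])

    def well_defined(self, population: str) -> bool:
        return bool(self.table.loc[population, "well_defined"])

    def restrict(self, populations: Sequence[str]) -> "PopulationMetadata":
        return PopulationMetadata(self.table.loc[list(populations)].copy())


def read_metadata(path) -> PopulationMetadata:
    df = pd.read_csv(path, dtype={"population": str, "name": str, "group": str, "region": str})
    if "population" not in df.columns:
        raise ParseError(f"{path}: missing 'population' column")
    df["well_defined"] = df["well_defined"].map(
        lambda x: str(x).strip().lower() in ("1", "true", "yes")
    )
    return PopulationMetadata(df.set_index("population"))


def write_metadata(meta: PopulationMetadata, path) -> None:
    out = meta.table.reset_index().rename(columns={"index": "population"})
    out.to_csv(path, index=False)


@dataclass
class HierarchyConfig:
    """Population -> geographic-group assignment defining the among-groups
    stratum of the hierarchical variance analysis."""

    assignment: dict[str, str]
    group_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        groups = list(dict.fromkeys(self.assignment.values()))
        if not self.group_order:
            self.group_order = groups
        missing = set(groups) - set(self.group_order)
        if missing:
            raise ValidationError(f"group_order omits groups {sorted(missing)}")
        if len(groups) < 2:
            raise ValidationError("hierarchy needs at least 2 groups")

    @classmethod
    def from_metadata(cls, meta: PopulationMetadata, populations: Sequence[str] | None = None,
                      group_order: Sequence[str] | None = None) -> "HierarchyConfig":
        pops = list(populations) if populations is not None else meta.populations
        return cls({p: meta.group(p) for p in pops}, list(group_order or []))

    def groups_of(self, populations: Sequence[str]) -> list[str]:
        out = []
        for p in populations:
            if p not in self.assignment:
                raise ValidationError(f"population {p!r} missing from hierarchy")
            out.append(self.assignment[p])
        return out

    def members(self, group: str) -> list[str]:
        return [p for p, g in self.assignment.items() if g == group]
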