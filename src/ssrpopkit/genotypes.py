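"""Multiallelic genotype matrices and file I/O.

The central container is :class:`GenotypeMatrix`: individuals x loci, two
allele slots per cell.  Allele codes are fragment sizes in base pairs
(positive integers); two sentinel states exist besides real sizes:

* ``MISSING`` -- no call at all (both slots must be missing together);
* ``NULL`` -- a real, scorable allele state (a non-amplifying allele observed
  as absence of product).  NULL is *not* missing data: it enters allele
  counts and frequencies as its own allele class, matching codominant
  999/999 scoring of null homozygotes.

Three text dialects are supported: Genepop 4.x, STRUCTURE (two rows per
individual, missing = -9) and a simple CSV with "a/b" cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: sentinel for a missing (uncalled) allele slot
MISSING: int = -1
#: sentinel for the null (non-amplifying) allele, a real allele state
NULL: int = -2

_STRUCTURE_MISSING = -9
_STRUCTURE_NULL = 999


class GenotypeParseError(ValueError):
    """Raised when an input file violates its declared dialect."""


class GenotypeValidationError(ValueError):
    """Raised when parsed content violates a GenotypeMatrix invariant."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci genotype table with two allele slots per cell.

    Parameters
    ----------
    individuals, loci
        Unique identifiers for rows and columns.
    calls
        int array of shape ``(n_individuals, n_loci, 2)`` holding bp sizes
        or the ``MISSING`` / ``NULL`` sentinels.
    populations
        Optional map individual -> population label.
    """

    individuals: list[str]
    loci: list[str]
    calls: np.ndarray
    populations: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int32)
        if self.calls.shape != (len(self.individuals), len(self.loci), 2):
            raise GenotypeValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        if len(set(self.individuals)) != len(self.individuals):
            raise GenotypeValidationError("duplicate individual identifiers")
        if len(set(self.loci)) != len(self.loci):
            raise GenotypeValidationError("duplicate locus identifiers")
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            i, j = np.argwhere(half)[0]
            raise GenotypeValidationError(
                f"half-missing cell at individual {self.individuals[i]!r}, "
                f"locus {self.loci[j]!r}"
            )
        bad = (self.calls < NULL) | (self.calls == 0)
        if bad.any():
            raise GenotypeValidationError("allele codes must be positive bp sizes, NULL or MISSING")
        # canonical unordered representation: slots sorted ascending
        self.calls = np.sort(self.calls, axis=2)

    # -- basic accessors -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, locus: str) -> int:
        return self.loci.index(locus)

    def individual_index(self, individual: str) -> int:
        return self.individuals.index(individual)

    def subset(self, individuals=None, loci=None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given identifiers (order kept)."""
        inds = list(individuals) if individuals is not None else self.individuals
        locs = list(loci) if loci is not None else self.loci
        ii = [self.individual_index(i) for i in inds]
        jj = [self.locus_index(l) for l in locs]
        pops = None
        if self.populations is not None:
            pops = {i: self.populations[i] for i in inds if i in self.populations}
        return GenotypeMatrix(inds, locs, self.calls[np.ix_(ii, jj)], pops)

    def missing_mask(self) -> np.ndarray:
        """Boolean (individual, locus) mask of fully missing cells."""
        return (self.calls == MISSING).all(axis=2)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class LinkageMap:
    """Marker -> (linkage group, position in cM)."""

    entries: dict[str, tuple[str, float]]

    def __post_init__(self) -> None:
        for marker, (lg, pos) in self.entries.items():
            if pos < 0:
                raise ValueError(f"negative cM position for {marker!r}")

    def linkage_group(self, marker: str) -> str:
        return self.entries[marker][0]

    def position(self, marker: str) -> float:
        return self.entries[marker][1]

    def __contains__(self, marker: str) -> bool:
        return marker in self.entries

    @classmethod
    def read_tsv(cls, path) -> "LinkageMap":
        entries = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#") or (lineno == 1 and line.lower().startswith("marker")):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise GenotypeParseError(f"{path}:{lineno}: expected 3 tab-separated fields")
                marker, lg, cm = parts
                if marker in entries:
                    raise GenotypeParseError(f"{path}:{lineno}: duplicate marker {marker!r}")
                entries[marker] = (lg, float(cm))
        return cls(entries)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("marker\tlinkage_group\tcM\n")
            for marker, (lg, cm) in self.entries.items():
                fh.write(f"{marker}\t{lg}\t{cm:g}\n")


@dataclass
class AlleleFrequencyTable:
    """Per (population, locus) allele frequency vectors.

    ``freqs[(pop, locus)]`` maps allele code -> frequency; ``n_genes`` holds
    the number of non-missing allele copies behind each vector.  A
    (population, locus) with no called copies is *undefined*: it appears in
    ``undefined`` and not in ``freqs``.
    """

    populations: list[str]
    loci: list[str]
    freqs: dict[tuple[str, str], dict[int, float]]
    n_genes: dict[tuple[str, str], int]
    undefined: set = field(default_factory=set)

    def alleles(self, locus: str) -> list[int]:
        """All allele codes seen at a locus, pooled over populations."""
        seen = set()
        for pop in self.populations:
            seen.update(self.freqs.get((pop, locus), {}))
        return sorted(seen)

    def pooled(self, locus: str) -> tuple[dict[int, float], int]:
        """Gene-count-weighted pooled frequencies and total n_genes at a locus."""
        counts: dict[int, float] = {}
        total = 0
        for pop in self.populations:
            key = (pop, locus)
            if key in self.undefined:
                continue
            n = self.n_genes[key]
            total += n
            for a, f in self.freqs[key].items():
                counts[a] = counts.get(a, 0.0) + f * n
        if total == 0:
            return {}, 0
        return {a: c / total for a, c in counts.items()}, total


# ---------------------------------------------------------------------------
# frequencies


def allele_frequencies(gm: GenotypeMatrix, grouping: dict[str, str] | None = None) -> AlleleFrequencyTable:
    """Count allele frequencies per population and locus.

    MISSING slots are excluded from gene counts; NULL is counted as one
    allele class.  Populations with zero called copies at a locus are
    flagged undefined rather than raising.
    """
    if grouping is None:
        grouping = gm.populations or {i: "pop1" for i in gm.individuals}
    for ind in grouping:
        if ind not in gm.individuals:
            raise KeyError(f"individual {ind!r} in grouping but not in matrix")
    pops = sorted(set(grouping.values()))
    idx_by_pop = {p: [gm.individual_index(i) for i in gm.individuals if grouping.get(i) == p] for p in pops}

    freqs: dict[tuple[str, str], dict[int, float]] = {}
    n_genes: dict[tuple[str, str], int] = {}
    undefined = set()
    for j, locus in enumerate(gm.loci):
        col = gm.calls[:, j, :]
        for pop in pops:
            sl = col[idx_by_pop[pop]].ravel()
            sl = sl[sl != MISSING]
            key = (pop, locus)
            n_genes[key] = sl.size
            if sl.size == 0:
                undefined.add(key)
                continue
            vals, counts = np.unique(sl, return_counts=True)
            freqs[key] = {int(v): c / sl.size for v, c in zip(vals, counts)}
    return AlleleFrequencyTable(pops, list(gm.loci), freqs, n_genes, undefined)


def minor_allele_frequency(freqs: AlleleFrequencyTable, locus: str) -> float:
    """Frequency of the rarest segregating allele, pooled over populations.

    Returns 0.0 for a monomorphic locus; raises if the locus has no defined
    frequencies anywhere.
    """
    if locus not in freqs.loci:
        raise KeyError(f"locus {locus!r} not in table")
    pooled, n = freqs.pooled(locus)
    if n == 0:
        raise ValueError(f"frequencies undefined at locus {locus!r}")
    if len(pooled) < 2:
        return 0.0
    return min(pooled.values())


# ---------------------------------------------------------------------------
# I/O

_FORMATS = ("genepop", "structure", "csv")


def read_genotypes(path, format: str) -> GenotypeMatrix:
    """Read a genotype matrix in one of the supported dialects.

    Genepop numeric codes 999 -> NULL, 0000 -> MISSING; STRUCTURE -9 ->
    MISSING, 999 -> NULL; CSV "?" -> MISSING, "999" -> NULL.
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    path = Path(path)
    if format == "csv":
        return _read_csv(path)
    if format == "structure":
        return _read_structure(path)
    return _read_genepop(path)


def write_genotypes(gm: GenotypeMatrix, path, format: str) -> None:
    """Write ``gm`` so that :func:`read_genotypes` recovers it exactly."""
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    path = Path(path)
    if format == "csv":
        _write_csv(gm, path)
    elif format == "structure":
        _write_structure(gm, path)
    else:
        _write_genepop(gm, path)


# -- CSV dialect: id[,pop],locus cells "a/b" --------------------------------


def _format_allele_csv(a: int) -> str:
    if a == MISSING:
        return "?"
    if a == NULL:
        return "999"
    return str(a)


def _parse_allele_csv(tok: str, where: str) -> int:
    tok = tok.strip()
    if tok == "?":
        return MISSING
    if tok == "999":
        return NULL
    try:
        v = int(tok)
    except ValueError:
        raise GenotypeParseError(f"{where}: bad allele token {tok!r}") from None
    if v <= 0:
        raise GenotypeParseError(f"{where}: allele size must be positive, got {tok!r}")
    return v


def _read_csv(path: Path) -> GenotypeMatrix:
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh]
    if not lines:
        raise GenotypeParseError(f"{path}:1: empty file")
    header = lines[0].split(",")
    has_pop = len(header) > 1 and header[1].strip().lower() in ("pop", "population")
    loci = [h.strip() for h in header[(2 if has_pop else 1):]]
    individuals, rows, pops = [], [], {}
    for lineno, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != len(header):
            raise GenotypeParseError(f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}")
        ind = parts[0].strip()
        if has_pop:
            pops[ind] = parts[1].strip()
        cells = parts[(2 if has_pop else 1):]
        row = []
        for locus, cell in zip(loci, cells):
            where = f"{path}:{lineno} ({locus})"
            cell = cell.strip()
            if cell in ("?", "?/?"):
                row.append((MISSING, MISSING))
                continue
            toks = cell.split("/")
            if len(toks) != 2:
                raise GenotypeParseError(f"{where}: cell {cell!r} is not 'a/b'")
            a, b = (_parse_allele_csv(t, where) for t in toks)
            if (a == MISSING) != (b == MISSING):
                raise GenotypeValidationError(f"{where}: half-missing cell {cell!r}")
            row.append((a, b))
        individuals.append(ind)
        rows.append(row)
    calls = np.array(rows, dtype=np.int32).reshape(len(individuals), len(loci), 2)
    return GenotypeMatrix(individuals, loci, calls, pops or None)


def _write_csv(gm: GenotypeMatrix, path: Path) -> None:
    has_pop = gm.populations is not None
    with open(path, "w") as fh:
        head = ["id"] + (["pop"] if has_pop else []) + list(gm.loci)
        fh.write(",".join(head) + "\n")
        for i, ind in enumerate(gm.individuals):
            cells = []
            for j in range(gm.n_loci):
                a, b = gm.calls[i, j]
                if a == MISSING:
                    cells.append("?/?")
                else:
                    cells.append(f"{_format_allele_csv(int(a))}/{_format_allele_csv(int(b))}")
            row = [ind] + ([gm.populations.get(ind, "")] if has_pop else []) + cells
            fh.write(",".join(row) + "\n")


# -- STRUCTURE dialect: two rows per individual -----------------------------


def _read_structure(path: Path) -> GenotypeMatrix:
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    if not lines:
        raise GenotypeParseError(f"{path}:1: empty file")
    loci = lines[0].split()
    body = lines[1:]
    if len(body) % 2:
        raise GenotypeParseError(f"{path}: odd number of genotype rows")
    individuals, rows, pops = [], [], {}
    for k in range(0, len(body), 2):
        r1, r2 = body[k].split(), body[k + 1].split()
        lineno = k + 2
        # optional population column between id and alleles
        has_pop = len(r1) == len(loci) + 2
        if not has_pop and len(r1) != len(loci) + 1:
            raise GenotypeParseError(f"{path}:{lineno}: expected {len(loci)} allele fields")
        if r1[: 2 if has_pop else 1] != r2[: 2 if has_pop else 1] or len(r1) != len(r2):
            raise GenotypeParseError(f"{path}:{lineno}: row pair mismatch for {r1[0]!r}")
        ind = r1[0]
        if has_pop:
            pops[ind] = r1[1]
        off = 2 if has_pop else 1
        row = []
        for j in range(len(loci)):
            a, b = int(r1[off + j]), int(r2[off + j])
            a = MISSING if a == _STRUCTURE_MISSING else (NULL if a == _STRUCTURE_NULL else a)
            b = MISSING if b == _STRUCTURE_MISSING else (NULL if b == _STRUCTURE_NULL else b)
            if (a == MISSING) != (b == MISSING):
                raise GenotypeValidationError(f"{path}:{lineno}: half-missing cell at locus {loci[j]!r}")
            row.append((a, b))
        individuals.append(ind)
        rows.append(row)
    calls = np.array(rows, dtype=np.int32).reshape(len(individuals), len(loci), 2)
    return GenotypeMatrix(individuals, loci, calls, pops or None)


def _write_structure(gm: GenotypeMatrix, path: Path) -> None:
    def code(a: int) -> str:
        if a == MISSING:
            return str(_STRUCTURE_MISSING)
        if a == NULL:
            return str(_STRUCTURE_NULL)
        return str(a)

    has_pop = gm.populations is not None
    with open(path, "w") as fh:
        fh.write(" ".join(gm.loci) + "\n")
        for i, ind in enumerate(gm.individuals):
            prefix = [ind] + ([gm.populations.get(ind, "1")] if has_pop else [])
            for slot in (0, 1):
                fh.write(" ".join(prefix + [code(int(gm.calls[i, j, slot])) for j in range(gm.n_loci)]) + "\n")


# -- Genepop dialect --------------------------------------------------------
#
# Allele sizes are mapped to 3-digit codes per locus (ascending size -> 001,
# 002, ...); 999 encodes the null allele and 000 a missing slot.  The
# size<->code table is written to a "<file>.alleles.tsv" sidecar, which the
# reader uses (when present) to restore bp sizes losslessly.


def _read_genepop(path: Path) -> GenotypeMatrix:
    sidecar = path.with_name(path.name + ".alleles.tsv")
    size_of: dict[tuple[str, int], int] = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            next(fh)
            for line in fh:
                locus, code, size = line.split("\t")
                size_of[(locus, int(code))] = int(size)

    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh]
    if len(lines) < 2:
        raise GenotypeParseError(f"{path}:1: truncated Genepop file")
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        for tok in lines[i].split(","):
            if tok.strip():
                loci.append(tok.strip())
        i += 1
    individuals, rows, pops = [], [], {}
    pop_idx = 0
    while i < len(lines):
        if lines[i].strip().lower() == "pop":
            pop_idx += 1
            i += 1
            continue
        line = lines[i]
        if not line.strip():
            i += 1
            continue
        if "," not in line:
            raise GenotypeParseError(f"{path}:{i + 1}: missing comma after individual name")
        name, rest = line.split(",", 1)
        ind = name.strip()
        cells = rest.split()
        if len(cells) != len(loci):
            raise GenotypeParseError(f"{path}:{i + 1}: expected {len(loci)} genotype fields, got {len(cells)}")
        row = []
        for locus, cell in zip(loci, cells):
            if len(cell) not in (4, 6) or not cell.isdigit():
                raise GenotypeParseError(f"{path}:{i + 1}: bad Genepop cell {cell!r}")
            w = len(cell) // 2
            codes = (int(cell[:w]), int(cell[w:]))
            null_code = 10 ** w - 1  # 99 or 999
            alleles = []
            for c in codes:
                if c == 0:
                    alleles.append(MISSING)
                elif c == null_code:
                    alleles.append(NULL)
                else:
                    alleles.append(size_of.get((locus, c), c))
            a, b = alleles
            if (a == MISSING) != (b == MISSING):
                raise GenotypeValidationError(f"{path}:{i + 1}: half-missing cell {cell!r}")
            row.append((a, b))
        individuals.append(ind)
        pops[ind] = f"pop{pop_idx}"
        rows.append(row)
        i += 1
    calls = np.array(rows, dtype=np.int32).reshape(len(individuals), len(loci), 2)
    return GenotypeMatrix(individuals, loci, calls, pops or None)


def _write_genepop(gm: GenotypeMatrix, path: Path) -> None:
    # build per-locus size -> 3-digit code tables
    code_of: dict[tuple[str, int], int] = {}
    for j, locus in enumerate(gm.loci):
        sizes = sorted({int(a) for a in gm.calls[:, j, :].ravel() if a > 0})
        if len(sizes) > 998:
            raise ValueError(f"locus {locus!r} has more than 998 alleles")
        for k, s in enumerate(sizes, start=1):
            code_of[(locus, s)] = k

    def cell(a: int, b: int, locus: str) -> str:
        def code(x: int) -> int:
            if x == MISSING:
                return 0
            if x == NULL:
                return 999
            return code_of[(locus, x)]

        return f"{code(a):03d}{code(b):03d}"

    # group individuals by population, preserving first-seen order
    if gm.populations:
        pop_order = list(dict.fromkeys(gm.populations.get(i, "pop1") for i in gm.individuals))
        groups = [[i for i in gm.individuals if gm.populations.get(i, "pop1") == p] for p in pop_order]
    else:
        groups = [list(gm.individuals)]

    with open(path, "w") as fh:
        fh.write("ssrpopkit genotype export\n")
        for locus in gm.loci:
            fh.write(locus + "\n")
        for members in groups:
            if not members:
                continue
            fh.write("Pop\n")
            for ind in members:
                i = gm.individual_index(ind)
                cells = [cell(int(gm.calls[i, j, 0]), int(gm.calls[i, j, 1]), gm.loci[j]) for j in range(gm.n_loci)]
                fh.write(f"{ind} ,  " + " ".join(cells) + "\n")

    with open(path.with_name(path.name + ".alleles.tsv"), "w") as fh:
        fh.write("locus\tcode\tsize_bp\n")
        for (locus, size), code in sorted(code_of.items(), key=lambda kv: (gm.loci.index(kv[0][0]), kv[1])):
            fh.write(f"{locus}\t{code:03d}\t{size}\n")


def random_matrix(rng: np.random.Generator, n_ind: int = 8, n_loci: int = 5,
                  missing_rate: float = 0.1, null_rate: float = 0.05) -> GenotypeMatrix:
    """A random valid matrix, used by round-trip tests and examples."""
    sizes = rng.integers(100, 300, size=(n_ind, n_loci, 2)).astype(np.int32)
    nulls = rng.random((n_ind, n_loci, 2)) < null_rate
    sizes[nulls] = NULL
    miss = rng.random((n_ind, n_loci)) < missing_rate
    sizes[miss] = MISSING
    individuals = [f"ind{i:03d}" for i in range(n_ind)]
    loci = [f"Lu{j + 1}" for j in range(n_loci)]
    # contiguous population blocks (the Genepop dialect groups by population)
    pops = {ind: f"pop{1 + (i >= n_ind // 2)}" for i, ind in enumerate(individuals)}
    return GenotypeMatrix(individuals, loci, sizes, pops)
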