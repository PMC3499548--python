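"""Diploid microsatellite genotype tables: data model, I/O and pooled sampling.

The central container is :class:`GenotypeMatrix`, an individuals x loci table of
unordered diploid allele-size pairs (integer repeat units or fragment lengths)
with a sampling-site label per individual.  Two text dialects are supported:

* **Genepop** — title line, one locus name per line, ``Pop`` blocks; alleles
  encoded as 2- or 3-digit pairs, ``0`` meaning missing.  A site label may
  follow ``Pop`` on the same line; bare ``Pop`` lines get ``pop1``, ``pop2``...
* **delimited** — a TSV/CSV table with columns ``individual``, ``site`` and one
  column per locus holding ``a1/a2`` (empty cell or ``0/0`` = missing).

Pooled sampling (:func:`pool_samples`) draws individuals without replacement
from a union of sites and relabels them to a single group — the sampling scheme
used to test whether population structure alone can mimic a bottleneck.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "SampleGroup",
    "GenotypeError",
    "read_genotype_table",
    "write_genotype_table",
    "pool_samples",
]

MISSING = 0  # allele code for a missing call (Genepop convention)


class GenotypeError(ValueError):
    """Raised for malformed genotype input or invariant violations."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid allele-size table with site labels.

    Parameters
    ----------
    individuals
        Unique identifier per individual (length n).
    sites
        Site label per individual (length n).
    loci
        Locus names (length L).
    calls
        Integer array of shape (n, L, 2).  A call is either two positive
        allele sizes (stored sorted, the pair is unordered) or ``(0, 0)``
        meaning missing.
    """

    individuals: list[str]
    sites: list[str]
    loci: list[str]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.individuals = [str(i) for i in self.individuals]
        self.sites = [str(s) for s in self.sites]
        self.loci = [str(l) for l in self.loci]
        calls = np.asarray(self.calls, dtype=np.int64)
        if calls.ndim != 3 or calls.shape[2] != 2:
            raise GenotypeError("calls must have shape (n_individuals, n_loci, 2)")
        calls = np.sort(calls, axis=2)  # unordered pair -> canonical order
        self.calls = calls
        self.validate()

    # -- invariants -----------------------------------------------------------
    def validate(self) -> None:
        n, L = self.calls.shape[:2]
        if n < 1 or L < 1:
            raise GenotypeError("need at least one individual and one locus")
        if len(self.individuals) != n or len(self.sites) != n:
            raise GenotypeError("individuals/sites length does not match calls")
        if len(self.loci) != L:
            raise GenotypeError("loci length does not match calls")
        if len(set(self.individuals)) != n:
            raise GenotypeError("individual identifiers must be unique")
        if any(not s for s in self.sites):
            raise GenotypeError("every individual needs a non-empty site label")
        a1, a2 = self.calls[..., 0], self.calls[..., 1]
        missing = (a1 == MISSING) & (a2 == MISSING)
        half = (a1 == MISSING) ^ (a2 == MISSING)
        if half.any():
            i, j = np.argwhere(half)[0]
            raise GenotypeError(
                f"call for {self.individuals[i]} at {self.loci[j]} has one "
                "missing allele; a call is either complete or fully missing"
            )
        if (self.calls[~missing] <= 0).any():
            raise GenotypeError("allele sizes must be positive integers")

    # -- conveniences ---------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    @property
    def site_set(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sites:
            seen.setdefault(s)
        return list(seen)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L) array, True where the call is missing."""
        return (self.calls[..., 0] == MISSING) & (self.calls[..., 1] == MISSING)

    def site_indices(self, site: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.sites, dtype=object) == site)
        if idx.size == 0:
            raise GenotypeError(f"unknown site {site!r}")
        return idx

    def subset(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            [self.individuals[i] for i in idx],
            [self.sites[i] for i in idx],
            list(self.loci),
            self.calls[idx].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy DataFrame with ``individual``, ``site`` and ``a1/a2`` columns."""
        data: dict[str, list] = {
            "individual": self.individuals,
            "site": self.sites,
        }
        miss = self.missing_mask()
        for j, locus in enumerate(self.loci):
            col = [
                "" if miss[i, j] else f"{self.calls[i, j, 0]}/{self.calls[i, j, 1]}"
                for i in range(self.n_individuals)
            ]
            data[locus] = col
        return pd.DataFrame(data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.sites == other.sites
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )


@dataclass(frozen=True)
class SampleGroup:
    """A pooled-sample definition: draw ``target_n`` individuals from sites.

    Mirrors the pooled sampling scheme used to probe structure confounds:
    genotypes from several differentiated sites are merged into one sample so
    that the genealogy reflects the metapopulation rather than a single deme.
    """

    name: str
    member_sites: frozenset[str]
    target_n: int

    def __init__(self, name: str, member_sites: Iterable[str], target_n: int):
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "member_sites", frozenset(str(s) for s in member_sites))
        object.__setattr__(self, "target_n", int(target_n))
        if not self.member_sites:
            raise GenotypeError("member_sites must be non-empty")
        if self.target_n < 1:
            raise GenotypeError("target_n must be >= 1")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _as_text_stream(source) -> IO[str]:
    if isinstance(source, str):
        if "\n" in source:
            return io.StringIO(source)
        return open(source, "r")
    if hasattr(source, "read"):
        return source
    return open(str(source), "r")


def _parse_genepop_call(token: str, lineno: int) -> tuple[int, int]:
    if not token.isdigit() or len(token) not in (4, 6):
        raise GenotypeError(
            f"line {lineno}: genotype token {token!r} is not a 4- or 6-digit code"
        )
    w = len(token) // 2
    a1, a2 = int(token[:w]), int(token[w:])
    if (a1 == 0) != (a2 == 0):
        raise GenotypeError(
            f"line {lineno}: half-missing genotype {token!r}; use 0 for both alleles"
        )
    return a1, a2


def _read_genepop(stream: IO[str]) -> GenotypeMatrix:
    lines = stream.read().splitlines()
    if len(lines) < 3:
        raise GenotypeError("genepop input too short: need title, loci and a Pop block")
    # locus names: one per line, or comma-separated on the second line
    loci: list[str] = []
    pos = 1
    pop_re = re.compile(r"^\s*pop(\s+(?P<label>\S.*?))?\s*$", re.IGNORECASE)
    while pos < len(lines) and not pop_re.match(lines[pos]):
        chunk = [t.strip() for t in lines[pos].split(",") if t.strip()]
        loci.extend(chunk)
        pos += 1
    if not loci:
        raise GenotypeError("no locus names found before the first Pop line")
    individuals: list[str] = []
    sites: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    site_label = None
    n_pops = 0
    for lineno, raw in enumerate(lines[pos:], start=pos + 1):
        if not raw.strip():
            continue
        m = pop_re.match(raw)
        if m:
            n_pops += 1
            site_label = m.group("label") or f"pop{n_pops}"
            continue
        if site_label is None:
            raise GenotypeError(f"line {lineno}: genotype row before any Pop line")
        if "," not in raw:
            raise GenotypeError(f"line {lineno}: expected 'identifier , genotypes'")
        ident, _, rest = raw.partition(",")
        tokens = rest.split()
        if len(tokens) != len(loci):
            raise GenotypeError(
                f"line {lineno}: expected {len(loci)} genotypes, found {len(tokens)}"
            )
        individuals.append(ident.strip())
        sites.append(site_label)
        rows.append([_parse_genepop_call(t, lineno) for t in tokens])
    if not rows:
        raise GenotypeError("no genotype rows found")
    calls = np.array(rows, dtype=np.int64)
    return GenotypeMatrix(individuals, sites, loci, calls)


def _parse_pair(cell: str, lineno: int) -> tuple[int, int]:
    cell = cell.strip()
    if cell in ("", "0/0", "NA", "./."):
        return (MISSING, MISSING)
    m = re.fullmatch(r"(\d+)\s*/\s*(\d+)", cell)
    if not m:
        raise GenotypeError(f"line {lineno}: cannot parse genotype cell {cell!r}")
    a1, a2 = int(m.group(1)), int(m.group(2))
    if (a1 == 0) != (a2 == 0):
        raise GenotypeError(f"line {lineno}: half-missing genotype {cell!r}")
    return a1, a2


def _read_delimited(stream: IO[str]) -> GenotypeMatrix:
    text = stream.read()
    header_line = text.splitlines()[0] if text else ""
    sep = "\t" if "\t" in header_line else ","
    rows = [line.split(sep) for line in text.splitlines() if line.strip()]
    if len(rows) < 2:
        raise GenotypeError("delimited input needs a header and at least one row")
    header = [h.strip() for h in rows[0]]
    if len(header) < 3 or header[0] != "individual" or header[1] != "site":
        raise GenotypeError(
            "delimited header must start with 'individual', 'site', then loci"
        )
    loci = header[2:]
    individuals, sites, calls = [], [], []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise GenotypeError(
                f"line {lineno}: expected {len(header)} fields, found {len(row)}"
            )
        individuals.append(row[0].strip())
        sites.append(row[1].strip())
        calls.append([_parse_pair(c, lineno) for c in row[2:]])
    return GenotypeMatrix(individuals, sites, loci, np.array(calls, dtype=np.int64))


def read_genotype_table(source, format: str = "genepop") -> GenotypeMatrix:
    """Read a genotype table from a path, text blob or open stream.

    Parameters
    ----------
    source
        File path, text content (anything containing a newline) or open stream.
    format
        ``"genepop"`` or ``"delimited"``.
    """
    stream = _as_text_stream(source)
    try:
        if format == "genepop":
            return _read_genepop(stream)
        if format == "delimited":
            return _read_delimited(stream)
        raise GenotypeError(f"unknown format {format!r}")
    finally:
        if stream is not source and hasattr(stream, "close"):
            stream.close()


def write_genotype_table(g: GenotypeMatrix, format: str = "genepop",
                         title: str = "popcollapse genotypes") -> str:
    """Serialize a :class:`GenotypeMatrix`; the output re-reads to equality."""
    g.validate()
    if format == "genepop":
        if int(g.calls.max(initial=0)) > 999:
            raise GenotypeError("genepop encoding limited to 3-digit alleles (<=999)")
        out = [title]
        out.extend(g.loci)
        miss = g.missing_mask()
        current_site = None
        for i, (ind, site) in enumerate(zip(g.individuals, g.sites)):
            if site != current_site:
                out.append(f"Pop {site}")
                current_site = site
            toks = []
            for j in range(g.n_loci):
                if miss[i, j]:
                    toks.append("000000")
                else:
                    toks.append(f"{g.calls[i, j, 0]:03d}{g.calls[i, j, 1]:03d}")
            out.append(f"{ind} , " + " ".join(toks))
        return "\n".join(out) + "\n"
    if format == "delimited":
        frame = g.to_frame()
        return frame.to_csv(sep="\t", index=False)
    raise GenotypeError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Pooled sampling
# ---------------------------------------------------------------------------

def pool_samples(g: GenotypeMatrix, group: SampleGroup, seed: int) -> GenotypeMatrix:
    """Draw ``group.target_n`` individuals uniformly without replacement from the
    union of ``group.member_sites`` and relabel them to ``group.name``.

    Deterministic for a given ``seed``.  Individuals are physical samples, so
    drawing is without replacement and no identifier ever repeats.
    """
    unknown = group.member_sites - set(g.site_set)
    if unknown:
        raise GenotypeError(f"unknown member sites: {sorted(unknown)}")
    pool = [i for i, s in enumerate(g.sites) if s in group.member_sites]
    if not pool:
        raise GenotypeError("no individuals available in member_sites")
    if group.target_n > len(pool):
        raise GenotypeError(
            f"target_n={group.target_n} exceeds the {len(pool)} individuals "
            f"available in {sorted(group.member_sites)}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=group.target_n, replace=False)
    idx = [pool[k] for k in chosen]
    pooled = g.subset(idx)
    pooled.sites = [group.name] * pooled.n_individuals
    return pooled
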