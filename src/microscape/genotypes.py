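"""Diploid microsatellite genotype tables and file I/O.

Genotypes are stored per individual and locus as an unordered pair of
integer allele codes, or missing.  Two dialects are supported: genepop
(4- or 6-digit concatenated alleles, ``00``/``000`` meaning missing) and a
flat CSV with two columns per locus (``locus.1``, ``locus.2``; blank =
missing) plus optional coordinates and sex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeTable", "load_genotypes", "write_genotypes"]

MISSING = -1


@dataclass
class GenotypeTable:
    """Individuals x loci diploid allele calls with optional coordinates.

    ``calls`` has shape (n_individuals, n_loci, 2) of integer allele codes,
    with both entries ``MISSING`` (-1) for an untyped individual-locus.
    """

    individual_ids: list[str]
    loci: list[str]
    calls: np.ndarray
    x: np.ndarray | None = None
    y: np.ndarray | None = None
    sex: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=int)
        n, L = len(self.individual_ids), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls must have shape ({n}, {L}, 2), got {self.calls.shape}"
            )
        seen: set[str] = set()
        for iid in self.individual_ids:
            if iid in seen:
                raise ValueError(f"duplicate individual id: {iid!r}")
            seen.add(iid)
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            i, l = np.argwhere(half)[0]
            raise ValueError(
                f"individual {self.individual_ids[i]!r} locus {self.loci[l]!r}: "
                "exactly one allele missing (calls must be complete pairs)"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L): True where the individual-locus call is missing."""
        return (self.calls == MISSING).all(axis=2)

    def coords(self) -> np.ndarray:
        if self.x is None or self.y is None:
            raise ValueError("genotype table has no coordinates")
        return np.column_stack([self.x, self.y])

    def subset(self, ids: list[str]) -> "GenotypeTable":
        """Table restricted to the listed individuals, in the given order."""
        idx = {iid: k for k, iid in enumerate(self.individual_ids)}
        missing = [i for i in ids if i not in idx]
        if missing:
            raise KeyError(f"unknown individual ids: {missing}")
        sel = [idx[i] for i in ids]
        return GenotypeTable(
            individual_ids=list(ids),
            loci=list(self.loci),
            calls=self.calls[sel],
            x=None if self.x is None else self.x[sel],
            y=None if self.y is None else self.y[sel],
            sex=None if self.sex is None else [self.sex[k] for k in sel],
            meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# genepop dialect


def _parse_genepop(path) -> GenotypeTable:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ValueError("empty genepop file")
    # line 1 = title; locus names follow until the first POP
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        for name in lines[i].replace(",", " ").split():
            loci.append(name)
        i += 1
    if i == len(lines):
        raise ValueError("genepop file has no POP line")
    ids: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    digits = None
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if line.lower() == "pop":
            continue
        if "," not in line:
            raise ValueError(f"genepop individual line lacks comma: {line!r}")
        iid, rest = line.split(",", 1)
        iid = iid.strip()
        tokens = rest.split()
        if len(tokens) != len(loci):
            raise ValueError(
                f"individual {iid!r}: {len(tokens)} genotypes for {len(loci)} loci"
            )
        calls = []
        for tok, locus in zip(tokens, loci):
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise ValueError(
                    f"individual {iid!r} locus {locus!r}: bad genotype token {tok!r}"
                )
            d = len(tok) // 2
            if digits is None:
                digits = d
            a1, a2 = int(tok[:d]), int(tok[d:])
            calls.append(
                (MISSING, MISSING) if a1 == 0 and a2 == 0 else (a1, a2)
            )
            if (a1 == 0) != (a2 == 0):
                raise ValueError(
                    f"individual {iid!r} locus {locus!r}: half-missing call {tok!r}"
                )
        ids.append(iid)
        rows.append(calls)
    table = GenotypeTable(ids, loci, np.array(rows, dtype=int))
    table.meta["genepop_digits"] = digits or 3
    return table


def _write_genepop(table: GenotypeTable, path) -> None:
    d = int(table.meta.get("genepop_digits", 3))
    with open(path, "w") as fh:
        fh.write("microscape genotype export\n")
        for locus in table.loci:
            fh.write(locus + "\n")
        fh.write("POP\n")
        for k, iid in enumerate(table.individual_ids):
            toks = []
            for l in range(table.n_loci):
                a1, a2 = table.calls[k, l]
                if a1 == MISSING:
                    a1 = a2 = 0
                toks.append(f"{a1:0{d}d}{a2:0{d}d}")
            fh.write(f"{iid}, " + " ".join(toks) + "\n")


# ---------------------------------------------------------------------------
# CSV dialect: id, x, y, sex, locus.1, locus.2, ...


def _parse_csv(path) -> GenotypeTable:
    df = pd.read_csv(path, dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError("genotype CSV must have an 'id' column")
    allele_cols = [c for c in df.columns if c.endswith(".1") or c.endswith(".2")]
    loci: list[str] = []
    for c in allele_cols:
        base = c[:-2]
        if base not in loci:
            loci.append(base)
    for locus in loci:
        for suff in (".1", ".2"):
            if locus + suff not in df.columns:
                raise ValueError(f"locus {locus!r} missing column {locus + suff!r}")
    n = len(df)
    calls = np.full((n, len(loci), 2), MISSING, dtype=int)
    for l, locus in enumerate(loci):
        a1 = df[locus + ".1"]
        a2 = df[locus + ".2"]
        for k in range(n):
            v1, v2 = a1.iloc[k], a2.iloc[k]
            m1, m2 = pd.isna(v1), pd.isna(v2)
            if m1 != m2:
                raise ValueError(
                    f"individual {df['id'].iloc[k]!r} locus {locus!r}: "
                    "exactly one allele missing"
                )
            if not m1:
                calls[k, l] = (int(v1), int(v2))
    x = df["x"].to_numpy(float) if "x" in df.columns else None
    y = df["y"].to_numpy(float) if "y" in df.columns else None
    sex = df["sex"].fillna("unknown").tolist() if "sex" in df.columns else None
    return GenotypeTable(df["id"].tolist(), loci, calls, x=x, y=y, sex=sex)


def _write_csv(table: GenotypeTable, path) -> None:
    data: dict[str, object] = {"id": table.individual_ids}
    if table.x is not None:
        data["x"] = table.x
    if table.y is not None:
        data["y"] = table.y
    if table.sex is not None:
        data["sex"] = table.sex
    for l, locus in enumerate(table.loci):
        col1 = [a if a != MISSING else np.nan for a in table.calls[:, l, 0]]
        col2 = [a if a != MISSING else np.nan for a in table.calls[:, l, 1]]
        data[locus + ".1"] = pd.array(col1, dtype="Int64")
        data[locus + ".2"] = pd.array(col2, dtype="Int64")
    pd.DataFrame(data).to_csv(path, index=False)


def load_genotypes(source, dialect: str = "csv") -> GenotypeTable:
    """Load a genotype table from ``source`` in the named dialect."""
    if dialect == "genepop":
        return _parse_genepop(source)
    if dialect == "csv":
        return _parse_csv(source)
    raise ValueError(f"unknown genotype dialect: {dialect!r}")


def write_genotypes(table: GenotypeTable, path, dialect: str = "csv") -> None:
    """Write a genotype table; ``load_genotypes(write(...))`` round-trips."""
    if dialect == "genepop":
        _write_genepop(table, path)
    elif dialect == "csv":
        _write_csv(table, path)
    else:
        raise ValueError(f"unknown genotype dialect: {dialect!r}")
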