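"""Readers/writers for the formats the pipeline touches.

Individual trait tables and environment tables are plain CSV; microsatellite
genotypes come in Genepop (2- or 3-digit allele dialects); population trees are
Newick.  Tables are validated pandas DataFrames; trees are :class:`dendropy.Tree`
instances.  Population identity is a string key everywhere and any deterministic
ordering is lexicographic.
"""

from __future__ import annotations

import io
import logging
import re
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

TRAIT_COLUMNS = ["body_mass", "metabolic_rate", "excretion_rate", "boldness"]

#: physical bounds per trait: (low, high, low_inclusive)
_TRAIT_BOUNDS = {
    "body_mass": (0.0, np.inf, False),
    "metabolic_rate": (0.0, np.inf, True),
    "excretion_rate": (0.0, np.inf, True),
    "boldness": (0.0, 900.0, True),
}

BOLDNESS_MAX = 900.0


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def read_trait_table(path) -> pd.DataFrame:
    """Read and validate an individual-level trait CSV.

    Expected header: ``individual_id, population_id, body_mass, metabolic_rate,
    excretion_rate, boldness``.  Empty cells denote missing values and are kept
    as NaN, never zero-filled.  Units: body mass g, metabolic rate mg O2/hr,
    excretion rate ug NH4+/L/hr, boldness seconds in [0, 900].
    """
    df = pd.read_csv(path, dtype={"individual_id": str, "population_id": str})
    required = ["individual_id", "population_id"] + TRAIT_COLUMNS
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise FormatError(f"trait table missing columns: {missing_cols}")
    df = df[required].copy()
    return validate_trait_table(df)


def validate_trait_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a trait table already in memory (same contract as the reader)."""
    dup = df["individual_id"][df["individual_id"].duplicated()]
    if len(dup):
        raise FormatError(f"duplicate individual_id: {sorted(set(dup))}")
    if (df["population_id"].isna() | (df["population_id"] == "")).any():
        raise FormatError("empty population_id encountered")
    for trait in TRAIT_COLUMNS:
        vals = pd.to_numeric(df[trait], errors="coerce")
        bad_parse = df[trait].notna() & vals.isna()
        if bad_parse.any():
            row = int(np.flatnonzero(bad_parse)[0])
            raise FormatError(f"non-numeric {trait} in row {row}")
        low, high, low_incl = _TRAIT_BOUNDS[trait]
        oob = vals.notna() & (
            (vals < low) | (vals > high) | ((~low_incl) & (vals == low))
        )
        if oob.any():
            row = int(np.flatnonzero(oob)[0])
            raise FormatError(
                f"{trait} out of bounds in row {row}: value {vals.iloc[row]!r}, "
                f"allowed {'[' if low_incl else '('}{low}, {high}]"
            )
        df[trait] = vals
    return df.reset_index(drop=True)


def read_env_table(path, populations=None) -> pd.DataFrame:
    """Read the population environment CSV (temperature degC, predation ind/m2).

    If *populations* is given, every one of them must be present.
    """
    df = pd.read_csv(path, dtype={"population_id": str})
    for col in ("population_id", "temperature", "predation"):
        if col not in df.columns:
            raise FormatError(f"environment table missing column {col!r}")
    if df["population_id"].duplicated().any():
        raise FormatError("duplicate population_id in environment table")
    if (df["predation"] < 0).any():
        raise FormatError("negative predation value")
    if populations is not None:
        absent = sorted(set(populations) - set(df["population_id"]))
        if absent:
            raise FormatError(f"populations missing from environment table: {absent}")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Genepop


def read_genepop(path, pop_names=None) -> pd.DataFrame:
    """Parse a Genepop file into a long genotype table.

    Supports the 2- and 3-digit allele dialects; "00"/"000" encodes a missing
    allele.  Populations are labelled ``pop01``, ``pop02``, ... in POP-block
    order unless *pop_names* supplies explicit labels (a list, one per POP
    block) or is the string ``"prefix"`` (label = individual name up to the
    first underscore, the convention this package's writer uses).

    Returns a DataFrame with columns individual_id, population_id, locus_id,
    allele_a, allele_b (pandas nullable Int64; both alleles missing together).
    """
    text = Path(path).read_text(encoding="utf-8")
    return parse_genepop(text, pop_names=pop_names)


def parse_genepop(text: str, pop_names=None) -> pd.DataFrame:
    lines = [ln.rstrip() for ln in text.splitlines()]
    if not lines:
        raise FormatError("empty Genepop file")
    # first line is a title, then locus names until the first POP
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        ln = lines[i].strip()
        if ln:
            loci.extend(x.strip() for x in ln.split(",") if x.strip())
        i += 1
    if not loci:
        raise FormatError("no locus names before first POP line")
    if i == len(lines):
        raise FormatError("no POP line found")

    records = []
    pop_idx = 0
    ind_in_pop = 0
    for lineno in range(i, len(lines)):
        ln = lines[lineno].strip()
        if not ln:
            continue
        if ln.upper() == "POP":
            pop_idx += 1
            ind_in_pop = 0
            continue
        if "," not in ln:
            raise FormatError(f"line {lineno + 1}: expected 'name , genotypes'")
        name, geno = ln.split(",", 1)
        name = name.strip()
        fields = geno.split()
        if len(fields) != len(loci):
            raise FormatError(
                f"line {lineno + 1}: {len(fields)} genotype fields for "
                f"{len(loci)} loci"
            )
        ind_in_pop += 1
        if pop_names == "prefix":
            pop_id = name.split("_", 1)[0] if name else f"pop{pop_idx:02d}"
        elif pop_names is not None:
            pop_id = pop_names[pop_idx - 1]
        else:
            pop_id = f"pop{pop_idx:02d}"
        ind_id = name if name else f"{pop_id}_{ind_in_pop}"
        for locus, field in zip(loci, fields):
            if not re.fullmatch(r"\d+", field):
                raise FormatError(f"line {lineno + 1}: bad genotype field {field!r}")
            if len(field) not in (4, 6):
                raise FormatError(
                    f"line {lineno + 1}: genotype {field!r} is not 4 or 6 digits"
                )
            w = len(field) // 2
            a, b = int(field[:w]), int(field[w:])
            if a == 0 or b == 0:
                a = b = pd.NA  # "00"/"000" on either side = no call
            records.append((ind_id, pop_id, locus, a, b))

    df = pd.DataFrame.from_records(
        records,
        columns=["individual_id", "population_id", "locus_id", "allele_a", "allele_b"],
    )
    df["allele_a"] = df["allele_a"].astype("Int64")
    df["allele_b"] = df["allele_b"].astype("Int64")
    # disambiguate repeated individual names across populations
    df["individual_id"] = df["population_id"] + ":" + df["individual_id"]
    return df


def write_genepop(g: pd.DataFrame, path, title: str = "syndromekit export") -> None:
    """Write a long genotype table in 3-digit Genepop format."""
    loci = sorted(g["locus_id"].unique())
    pops = sorted(g["population_id"].unique())
    wide = g.pivot_table(
        index=["population_id", "individual_id"],
        columns="locus_id",
        values=["allele_a", "allele_b"],
        aggfunc="first",
    )
    out = [title]
    out.extend(loci)
    for pop in pops:
        out.append("POP")
        sub = wide.loc[pop]
        for ind in sorted(sub.index):
            codes = []
            for locus in loci:
                a = sub.loc[ind, ("allele_a", locus)]
                b = sub.loc[ind, ("allele_b", locus)]
                if pd.isna(a) or pd.isna(b):
                    codes.append("000000")
                else:
                    codes.append(f"{int(a):03d}{int(b):03d}")
            # strip the pop prefix added on read, if present
            name = ind.split(":", 1)[1] if ":" in str(ind) else str(ind)
            out.append(f"{name} , " + " ".join(codes))
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Newick trees


def read_newick(path_or_string) -> dendropy.Tree:
    """Read a Newick tree (file path or literal string)."""
    s = str(path_or_string)
    if s.lstrip().startswith("(") or s.rstrip().endswith(";"):
        tree = dendropy.Tree.get(data=s, schema="newick")
    else:
        tree = dendropy.Tree.get(path=s, schema="newick")
    _validate_tree(tree)
    return tree


def write_newick(tree: dendropy.Tree, path=None) -> str:
    """Serialise a tree to Newick with branch lengths; returns the string."""
    _validate_tree(tree)
    s = tree.as_string(schema="newick", suppress_rooting=True).strip()
    if not s.endswith(";"):
        s += ";"
    if path is not None:
        Path(path).write_text(s + "\n", encoding="utf-8")
    return s


def _validate_tree(tree: dendropy.Tree) -> None:
    labels = [t.label for t in tree.taxon_namespace]
    if len(labels) != len(set(labels)):
        raise FormatError("duplicate tip labels in tree")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            if not np.isfinite(edge.length):
                raise FormatError("non-finite branch length")
            if edge.length < 0:
                raise FormatError(f"negative branch length {edge.length}")


def tree_tip_labels(tree: dendropy.Tree) -> list[str]:
    return sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
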