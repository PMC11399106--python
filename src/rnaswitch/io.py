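"""Readers and writers for the standard file dialects.

FASTA (T mapped to U on ingest), SHAPE-style reactivity files
("position value", 1-based, -999/NA = missing), per-position mutation
count TSVs, screen count TSVs, dot-bracket strings, 6-column
connectivity tables (CT, 1-based), and the JSON records that carry
predictions, models, and the resolved run configuration.

Parse errors name the file, the line, and the violated rule.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .backends import dotbracket, parse_dotbracket  # re-exported  # noqa: F401
from .config import RunConfig
from .core import (
    ConflictingStemPair,
    ContractViolation,
    ReactivityRestraints,
    RnaSequence,
    SecondaryStructure,
)
from .reactivity import MutationRateProfile
from .screen import N_BINS, ScreenCounts


class ParseError(ValueError):
    def __init__(self, path, line: Optional[int], rule: str):
        loc = f"{path}:{line}" if line is not None else str(path)
        super().__init__(f"{loc}: {rule}")


# -- FASTA ------------------------------------------------------------


def read_fasta(path, ambiguous_as_unpaired: bool = False) -> list:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(path, None, "no FASTA records found")
    out = []
    for rec in records:
        try:
            out.append(
                RnaSequence.from_string(
                    rec.id, str(rec.seq), ambiguous_as_unpaired=ambiguous_as_unpaired
                )
            )
        except ContractViolation as exc:
            raise ParseError(path, None, f"record {rec.id!r}: {exc}") from exc
    return out


def write_fasta(seqs: list, path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


# -- reactivity files -------------------------------------------------


def read_reactivity_file(path, length: int) -> list:
    """SHAPE-dialect reactivity file -> per-position list (None = missing)."""
    values = [None] * length
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(path, ln, "expected 'position value'")
            try:
                pos = int(fields[0])
            except ValueError:
                raise ParseError(path, ln, f"bad position {fields[0]!r}") from None
            if not 1 <= pos <= length:
                raise ParseError(
                    path, ln, f"position {pos} outside 1..{length}"
                )
            raw = fields[1]
            if raw.upper() in ("NA", "NAN"):
                continue
            try:
                val = float(raw)
            except ValueError:
                raise ParseError(path, ln, f"bad value {raw!r}") from None
            if val <= -998:  # -999 marks missing data
                continue
            if val < 0:
                val = 0.0  # slightly negative baseline noise clips to zero
            values[pos - 1] = val
    return values


def write_reactivity_file(values: list, path) -> None:
    with open(path, "w") as fh:
        for i, v in enumerate(values, start=1):
            if v is None or (isinstance(v, float) and np.isnan(v)):
                fh.write(f"{i}\t-999\n")
            else:
                fh.write(f"{i}\t{v:.6f}\n")


def read_mutation_counts(path) -> MutationRateProfile:
    """TSV of (position, mutation_count, coverage), 1-based positions."""
    rows = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("position"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ParseError(
                    path, ln, "expected 'position mutation_count coverage'"
                )
            try:
                pos, cnt, cov = int(fields[0]), float(fields[1]), float(fields[2])
            except ValueError:
                raise ParseError(path, ln, f"non-numeric fields {fields[:3]}") from None
            if pos < 1:
                raise ParseError(path, ln, f"position {pos} must be >= 1")
            rows[pos] = (cnt, cov)
    if not rows:
        raise ParseError(path, None, "empty counts file")
    n = max(rows)
    counts = np.zeros(n)
    coverage = np.zeros(n)
    for pos, (cnt, cov) in rows.items():
        counts[pos - 1] = cnt
        coverage[pos - 1] = cov
    return MutationRateProfile(counts=counts, coverage=coverage)


# -- structures -------------------------------------------------------


def write_ct(seq: RnaSequence, structure: SecondaryStructure, path, energy=None) -> None:
    """6-column connectivity table, 1-based."""
    n = len(seq)
    partner = structure.partner_array(n)
    header = f"{n} {seq.id}" + (f" ENERGY = {energy}" if energy is not None else "")
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for i in range(n):
            fh.write(
                f"{i + 1} {seq.residues[i]} {i} {i + 2 if i + 2 <= n else 0} "
                f"{partner[i] + 1} {i + 1}\n"
            )


def read_ct(path) -> tuple:
    """Returns (RnaSequence, SecondaryStructure) from a 6-column CT file."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ParseError(path, 1, "empty CT file")
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise ParseError(path, 1, "bad CT header") from None
    name = lines[0].split()[1] if len(lines[0].split()) > 1 else "ct"
    residues = []
    pairs = []
    for ln, line in enumerate(lines[1 : n + 1], start=2):
        fields = line.split()
        if len(fields) < 6:
            raise ParseError(path, ln, "CT line needs 6 columns")
        idx = int(fields[0]) - 1
        residues.append(fields[1])
        partner = int(fields[4]) - 1
        if partner >= 0 and idx < partner:
            pairs.append((idx, partner))
    if len(residues) != n:
        raise ParseError(path, None, f"expected {n} residues, got {len(residues)}")
    seq = RnaSequence.from_string(name, "".join(residues))
    return seq, SecondaryStructure.from_pairs(pairs)


# -- screen counts ----------------------------------------------------

SCREEN_COLUMNS = ["variant", "bin", "replicate", "count"]


def read_screen_counts(path, material: str = "RNA") -> ScreenCounts:
    """Long TSV with columns variant, bin, replicate, count [, material]."""
    df = pd.read_csv(path, sep="\t")
    missing = set(SCREEN_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(path, 1, f"missing columns {sorted(missing)}")
    if "material" in df.columns:
        df = df[df["material"] == material]
        if df.empty:
            raise ParseError(path, None, f"no rows with material {material!r}")
    bad = df[~df["bin"].isin(range(1, N_BINS + 1))]
    if not bad.empty:
        ln = int(bad.index[0]) + 2  # +1 header, +1 1-based
        raise ParseError(
            path, ln, f"bin {bad.iloc[0]['bin']} outside the 1..{N_BINS} bin domain"
        )
    try:
        return ScreenCounts(table=df[SCREEN_COLUMNS].copy(), material=material)
    except ContractViolation as exc:
        raise ParseError(path, None, str(exc)) from exc


def write_screen_counts(counts: ScreenCounts, path) -> None:
    counts.table.to_csv(path, sep="\t", index=False)


# -- JSON records -----------------------------------------------------


def prediction_record(
    seq: RnaSequence,
    pair: Optional[ConflictingStemPair],
    config: RunConfig,
    conformations=None,
    features=None,
    barrier=None,
    k_values: Optional[dict] = None,
) -> dict:
    rec = {
        "sequence_id": seq.id,
        "length": len(seq),
        "switch": pair.as_dict() if pair is not None else None,
        "config": config.to_dict(),
    }
    if conformations is not None:
        rec["conformations"] = {
            "dotbracket1": dotbracket(conformations.conf1, len(seq)),
            "dotbracket2": dotbracket(conformations.conf2, len(seq)),
            "energy1": conformations.e1,
            "energy2": conformations.e2,
        }
    if barrier is not None:
        rec["activation_energy"] = barrier.activation_energy
        rec["barrier_method"] = f"{barrier.method} (upper bound)"
    if features is not None:
        rec["features"] = {
            "mean_fold_energy": features.mean_fold_energy,
            "activation_energy": features.activation_energy,
        }
    if k_values is not None:
        rec["k_values"] = {f"{i},{j}": v for (i, j), v in k_values.items()}
    return rec


def write_prediction(rec: dict, path) -> None:
    Path(path).write_text(json.dumps(rec, indent=2) + "\n")


def read_prediction(path) -> dict:
    rec = json.loads(Path(path).read_text())
    if rec.get("switch") is not None:
        rec["switch_pair"] = ConflictingStemPair.from_dict(rec["switch"])
    return rec


def write_model(model, config: RunConfig, path) -> None:
    Path(path).write_text(
        json.dumps({"model": model.as_dict(), "config": config.to_dict()}, indent=2)
        + "\n"
    )


def read_model(path):
    from .classifier import SwitchClassifier

    d = json.loads(Path(path).read_text())
    return SwitchClassifier.from_dict(d["model"]), RunConfig.from_dict(d["config"])


def restraints_from_file(
    path, length: int, slope_m: float = 1.8, intercept_b: float = -0.6
) -> ReactivityRestraints:
    return ReactivityRestraints(
        values=read_reactivity_file(path, length),
        slope_m=slope_m,
        intercept_b=intercept_b,
    )
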