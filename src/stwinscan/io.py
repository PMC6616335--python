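"""Shared readers/writers and run configuration.

Coordinate conventions: everything internal is 0-based half-open; GFF3
output is 1-based inclusive; BED output is 0-based half-open.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, TextIO

import yaml
from Bio import SeqIO

from .motifs import IUPAC_DNA, normalize_sequence
from .rules import DEFAULT_RULES, PROFILES, ConsensusProfile, DistanceRules

__all__ = [
    "InputError",
    "RunConfig",
    "read_fasta",
    "write_fasta",
    "write_bed",
    "load_rules",
    "load_config",
]


class InputError(ValueError):
    """User-supplied input could not be parsed or validated."""


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (optionally gzipped) FASTA; normalize and validate sequences.

    Sequences are uppercased, U folded to T, and every character checked
    against the IUPAC nucleotide alphabet; violations are reported with
    the file line number.  Record order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    with _open_text(path) as fh:
        first = fh.readline()
        if first and not first.startswith(">"):
            raise InputError(f"{path}:1: not a FASTA file (expected '>')")
    with _open_text(path) as fh:
        # track line numbers for error reporting
        line_no = 0
        seq_start_line: dict[str, int] = {}
        current = None
        for line in fh:
            line_no += 1
            if line.startswith(">"):
                current = line[1:].split()[0] if line[1:].strip() else ""
                if not current:
                    raise InputError(f"{path}:{line_no}: empty FASTA header")
                seq_start_line[current] = line_no
    records = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = normalize_sequence(str(rec.seq))
            bad = next((ch for ch in seq if ch not in IUPAC_DNA), None)
            if bad is not None:
                raise InputError(
                    f"{path}: record {rec.id!r} (near line "
                    f"{seq_start_line.get(rec.id, '?')}) contains invalid "
                    f"character {bad!r}"
                )
            records.append((rec.id, seq))
    if not records:
        raise InputError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[tuple[str, str]], handle: TextIO, width: int = 70) -> None:
    for rid, seq in records:
        handle.write(f">{rid}\n")
        for i in range(0, len(seq), width):
            handle.write(seq[i : i + width] + "\n")


def write_bed(calls, handle: TextIO) -> None:
    """BED6 of call total spans (0-based half-open, deterministic sort)."""
    rows = []
    for call in calls:
        s, e = call.total_span
        rows.append((call.seq_id or ".", s, e, call.label, 0, call.strand))
    rows.sort()
    for row in rows:
        handle.write("\t".join(str(x) for x in row) + "\n")


@dataclass(frozen=True)
class RunConfig:
    """Validated run settings; defaults are the published screen values."""

    profile: str = "relaxed"
    rules: DistanceRules = DEFAULT_RULES
    stw_kind: str = "D"
    stw_split: int = 5
    strand: str = "+"
    orf_filter: bool = False
    orf_window: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise InputError(f"unknown profile {self.profile!r}; choose from {sorted(PROFILES)}")
        if self.strand not in ("+", "-", "both"):
            raise InputError("strand must be '+', '-' or 'both'")
        if self.orf_window < 3:
            raise InputError("orf window must be >= 3 nt")

    @property
    def consensus(self) -> ConsensusProfile:
        return PROFILES[self.profile]


def load_rules(path: str | Path) -> DistanceRules:
    """Distance rules from a YAML mapping (missing keys keep defaults)."""
    with _open_text(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise InputError(f"{path}: rules file must be a YAML mapping")
    known = {"min_intron_len", "donor_bp_gap", "bp_acc_gap", "enforce_principle3"}
    unknown = set(data) - known
    if unknown:
        raise InputError(f"{path}: unknown rule keys {sorted(unknown)}")
    kwargs = {}
    for key in ("donor_bp_gap", "bp_acc_gap"):
        if key in data:
            window = data[key]
            if not (isinstance(window, (list, tuple)) and len(window) == 2):
                raise InputError(f"{path}: {key} must be a [min, max] pair")
            kwargs[key] = (int(window[0]), int(window[1]))
    if "min_intron_len" in data:
        kwargs["min_intron_len"] = int(data["min_intron_len"])
    if "enforce_principle3" in data:
        kwargs["enforce_principle3"] = bool(data["enforce_principle3"])
    try:
        return DistanceRules(**kwargs)
    except ValueError as exc:
        raise InputError(f"{path}: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    with _open_text(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise InputError(f"{path}: config must be a YAML mapping")
    rules = DEFAULT_RULES
    if "rules" in data:
        rules_data = data.pop("rules")
        if isinstance(rules_data, dict):
            kwargs = {}
            for key in ("donor_bp_gap", "bp_acc_gap"):
                if key in rules_data:
                    kwargs[key] = tuple(int(x) for x in rules_data[key])
            for key in ("min_intron_len",):
                if key in rules_data:
                    kwargs[key] = int(rules_data[key])
            if "enforce_principle3" in rules_data:
                kwargs["enforce_principle3"] = bool(rules_data["enforce_principle3"])
            rules = DistanceRules(**kwargs)
        else:
            raise InputError(f"{path}: 'rules' must be a mapping")
    try:
        return RunConfig(rules=rules, **data)
    except TypeError as exc:
        raise InputError(f"{path}: {exc}") from exc
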