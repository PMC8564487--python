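"""Readers and writers for the package's text formats.

Formats are deliberately plain: FASTA (60-column wrap, ';'/'#' comment
lines tolerated and used for provenance headers), one-peptide-per-line
text, and tab-separated tables ('.' renders a not-evaluable value, UTF-8,
no quoting). Peptide IDs come from FASTA headers and must be
whitespace-free.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import NonNaturalRegistry
from .motif import ALPHABET, PositionWeightMatrix, information_content
from .peptide import Peptide, parse_peptide

FASTA_WRAP = 60
NOT_EVALUABLE = "."


def read_peptides(
    path: str | Path, registry: NonNaturalRegistry | None = None
) -> dict[str, Peptide]:
    """Read peptides from FASTA or one-per-line text, keyed by ID.

    The format is sniffed from the first non-comment line ('>' means
    FASTA); line-format peptides get sequential ids p0001, p0002, ...
    Comment lines starting with ';' or '#' are skipped in both formats.
    """
    path = Path(path)
    lines = [
        ln.strip() for ln in path.read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith((";", "#"))
    ]
    if not lines:
        raise ValueError(f"no sequences in {path}")
    peptides: dict[str, Peptide] = {}
    if lines[0].startswith(">"):
        header: str | None = None
        chunks: list[str] = []

        def flush() -> None:
            if header is not None:
                if not chunks:
                    raise ValueError(f"empty record {header!r} in {path}")
                peptides[header] = parse_peptide("".join(chunks), registry)

        for ln in lines:
            if ln.startswith(">"):
                flush()
                header = ln[1:].split()[0] if ln[1:].split() else ""
                if not header:
                    raise ValueError(f"FASTA record without an ID in {path}")
                if header in peptides:
                    raise ValueError(f"duplicate FASTA ID {header!r} in {path}")
                chunks = []
            else:
                chunks.append(ln)
        flush()
    else:
        for i, ln in enumerate(lines, 1):
            peptides[f"p{i:04d}"] = parse_peptide(ln.split()[0], registry)
    return peptides


def write_fasta(
    records: Mapping[str, Peptide | str] | Sequence[tuple[str, Peptide | str]],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write peptides as FASTA, optionally preceded by ';' provenance lines."""
    items = records.items() if isinstance(records, Mapping) else records
    out = []
    if header_comment:
        out.extend(f"; {line}" for line in header_comment.splitlines())
    for pid, pep in items:
        if any(ch.isspace() for ch in pid):
            raise ValueError(f"FASTA IDs must be whitespace-free, got {pid!r}")
        seq = str(pep)
        out.append(f">{pid}")
        out.extend(seq[i:i + FASTA_WRAP] for i in range(0, len(seq), FASTA_WRAP))
    Path(path).write_text("\n".join(out) + "\n")


def format_value(x: object, decimals: int | None = None) -> str:
    """TSV cell rendering: '.' for missing/not-evaluable values."""
    if x is None:
        return NOT_EVALUABLE
    if isinstance(x, float) and math.isnan(x):
        return NOT_EVALUABLE
    if decimals is not None and isinstance(x, float):
        return f"{x:.{decimals}f}"
    return str(x)


def write_tsv(
    df: pd.DataFrame, path: str | Path, header_comment: str | None = None
) -> None:
    """Tab-separated output, '.' for NaN, no quoting, optional '#' header."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep=NOT_EVALUABLE)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=[NOT_EVALUABLE])


def pwm_to_frame(pwm: PositionWeightMatrix) -> pd.DataFrame:
    """PWM probabilities as a tidy positions x residues table."""
    df = pd.DataFrame(pwm.prob, columns=list(ALPHABET))
    df.insert(0, "position", np.arange(1, pwm.length + 1))
    return df


def logo_frame(pwm: PositionWeightMatrix) -> pd.DataFrame:
    """Long-format logo data: per position and residue, the bit contribution
    prob * info_bits (the letter height in a Shannon sequence logo)."""
    info = information_content(pwm)
    rows = [
        {
            "position": pos,
            "residue": aa,
            "probability": float(pwm.prob[pos - 1, j]),
            "bits": float(pwm.prob[pos - 1, j] * info[pos - 1]),
        }
        for pos in range(1, pwm.length + 1)
        for j, aa in enumerate(ALPHABET)
    ]
    return pd.DataFrame(rows)


def read_pwm(path: str | Path) -> PositionWeightMatrix:
    """Rebuild a PWM from the positions x residues probability TSV.

    Weighted frequencies are not stored in the TSV; the probabilities stand
    in for both (sufficient for scoring and consensus extraction).
    """
    from .motif import _information  # shared entropy helper

    df = read_tsv(path).sort_values("position")
    prob = df[list(ALPHABET)].to_numpy(dtype=float)
    prob = prob / prob.sum(axis=1, keepdims=True)
    return PositionWeightMatrix(
        length=prob.shape[0],
        alphabet=ALPHABET,
        weighted_freq=prob.copy(),
        prob=prob,
        info_bits=_information(prob),
        n_sequences=0,
        effective_n=0.0,
    )


def write_lines(peptides: Iterable[Peptide | str], path: str | Path) -> None:
    Path(path).write_text("\n".join(str(p) for p in peptides) + "\n")
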