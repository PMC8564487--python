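"""End-to-end design run: motif -> scaffold -> libraries -> scores -> report.

A :class:`RunConfig` fully determines a run: binder input (a peptide file
or a seeded synthetic set), motif parameters, the wild-type epitopes to
design against, and the variant lists. :func:`run_pipeline` executes the
chain deterministically and writes a fixed artifact set into the output
directory::

    pwm.tsv            position x residue probabilities
    logo.tsv           per-residue bit contributions for logo plotting
    motif.json         the anchor-consensus motif and run metadata
    designs.fasta      all designed peptides (substitutions in headers)
    design_report.tsv  substitution accounting per design
    scores.tsv         PWM log-odds for every natural design
    run.log            step-by-step log (no timestamps: reruns are
                       byte-identical)

Every artifact starts with a provenance header: tool version, config hash
and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .alphabet import NonNaturalRegistry, default_registry
from .binding import pwm_score
from .design import (
    DesignResult,
    INC_DEFAULTS,
    annotate_conservative,
    graft,
    inc_library,
    point_substitute,
    saturation_library,
)
from .io import read_peptides, write_fasta, write_tsv, pwm_to_frame, logo_frame
from .motif import anchor_consensus, build_pwm, sequence_weights
from .peptide import AnchorMap, H2DB_ANCHORS, Peptide, parse_peptide, parse_substitution
from .simulate import GeneratorSpec, sample_binders


@dataclass
class RunConfig:
    """Serializable description of one design run (the config echoes the run)."""

    allele: str = "H-2Db"
    anchor_positions: tuple[int, ...] = (2, 3, 5, 9)
    length: int = 9
    #: Path to a FASTA/line peptide file, or None to sample synthetic binders.
    peptides_path: str | None = None
    #: Synthetic binder count, used when peptides_path is None.
    n_binders: int = 250
    seed: int = 7
    pseudocount_strength: float = 50.0
    sequence_weighting: bool = True
    #: Wild-type epitopes to design against, name -> sequence.
    wt_epitopes: dict[str, str] = field(
        default_factory=lambda: {"E7": "RAHYNIVTF", "Trp2": "SVYDFFVWL"}
    )
    #: Heteroclitic point-variant notations per epitope (INC sets).
    inc_variants: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in INC_DEFAULTS.items()}
    )
    #: Position for the saturation (MIX) library; None disables it.
    saturation_position: int | None = 4
    out_dir: str = "run_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        data = dict(data)
        if "anchor_positions" in data:
            data["anchor_positions"] = tuple(data["anchor_positions"])
        if "inc_variants" in data:
            data["inc_variants"] = {
                k: tuple(v) for k, v in data["inc_variants"].items()
            }
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(_jsonable(self.to_dict()), sort_keys=True)
        )

    @property
    def anchor_map(self) -> AnchorMap:
        return AnchorMap(self.allele, self.length, frozenset(self.anchor_positions))

    @property
    def config_hash(self) -> str:
        # out_dir is a destination, not run content: the same design run
        # written to two directories hashes identically.
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(_jsonable(payload), sort_keys=True).encode()
        ).hexdigest()[:12]


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


class PipelineError(RuntimeError):
    """Fail-fast pipeline error (missing/empty input, inconsistent config)."""


@dataclass
class RunReport:
    """What a completed run produced."""

    config: RunConfig
    motif_display: str
    designs: dict[str, DesignResult]
    out_dir: Path
    artifacts: dict[str, Path]


def run_pipeline(
    config: RunConfig, registry: NonNaturalRegistry | None = None
) -> RunReport:
    """Execute the full design chain described by `config`.

    Deterministic: rerunning with an identical config yields byte-identical
    artifacts. On failure, partially written artifacts are removed.
    """
    registry = registry if registry is not None else default_registry()
    anchors = config.anchor_map
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    provenance = (
        f"pepscaffold v{__version__} | config_hash={config.config_hash} | "
        f"seed={config.seed}"
    )
    log_lines = [provenance]
    artifacts: dict[str, Path] = {}

    def artifact(name: str) -> Path:
        path = out_dir / name
        artifacts[name] = path
        return path

    try:
        # 1. binder set
        if config.peptides_path is not None:
            path = Path(config.peptides_path)
            if not path.exists():
                raise PipelineError(f"binder peptide file not found: {path}")
            try:
                binders = list(read_peptides(path).values())
            except ValueError as exc:
                raise PipelineError(str(exc)) from exc
            log_lines.append(f"loaded {len(binders)} binders from {path.name}")
        else:
            spec = GeneratorSpec(seed=config.seed, n=config.n_binders,
                                 length=config.length)
            binders = sample_binders(spec)
            log_lines.append(
                f"sampled {len(binders)} synthetic binders (seed={config.seed})"
            )

        # 2. weighted PWM and consensus motif
        weights = sequence_weights(binders) if config.sequence_weighting else None
        pwm = build_pwm(binders, weights, config.pseudocount_strength)
        motif = anchor_consensus(pwm, anchors)
        log_lines.append(f"anchor consensus motif: {motif.display}")

        write_tsv(pwm_to_frame(pwm), artifact("pwm.tsv"), provenance)
        write_tsv(logo_frame(pwm), artifact("logo.tsv"), provenance)

        # 3. designs: graft, INC variants, saturation library
        designs: dict[str, DesignResult] = {}
        report_rows = []

        def record(design_id: str, result: DesignResult) -> None:
            if design_id in designs:
                raise PipelineError(f"duplicate design id {design_id!r}")
            designs[design_id] = result
            subs = [annotate_conservative(s) for s in result.substitutions]
            report_rows.append(
                {
                    "design_id": design_id,
                    "wt": str(result.wt),
                    "designed": str(result.designed),
                    "design_kind": result.design_kind,
                    "substitutions": ",".join(s.notation for s in subs) or ".",
                    "conservative_flags": ",".join(
                        "." if s.conservative is None else str(s.conservative).lower()
                        for s in subs
                    ) or ".",
                }
            )

        for name, seq in config.wt_epitopes.items():
            wt = parse_peptide(seq, registry)
            if len(wt) != config.length:
                raise PipelineError(
                    f"epitope {name!r} has length {len(wt)}, expected {config.length}"
                )
            record(f"{name}-wt", DesignResult(wt, wt, (), "point"))
            record(f"{name}-scaff", graft(wt, motif, anchors))
            for notation in config.inc_variants.get(name, ()):
                sub = parse_substitution(notation, registry)
                record(
                    f"{name}-{notation}",
                    point_substitute(wt, sub.position, sub.new_residue),
                )
            if config.saturation_position is not None:
                library = saturation_library(wt, config.saturation_position)
                for member in library.members:
                    tag = member.notation[0] if member.substitutions else "wtmember"
                    record(f"{name}-MIX-{tag}", member)

        # 4. artifacts
        fasta_records = []
        for design_id, result in designs.items():
            subs = ",".join(result.notation) or "none"
            fasta_records.append((f"{design_id}|subs={subs}", result.designed))
        write_fasta(fasta_records, artifact("designs.fasta"), provenance)
        write_tsv(pd.DataFrame(report_rows), artifact("design_report.tsv"), provenance)

        score_rows = []
        for design_id, result in designs.items():
            if result.designed.is_natural:
                score = pwm_score(result.designed, pwm, design_id).logodds
                score_rows.append(
                    {"design_id": design_id, "sequence": str(result.designed),
                     "logodds": round(score, 6)}
                )
            else:
                score_rows.append(
                    {"design_id": design_id, "sequence": str(result.designed),
                     "logodds": float("nan")}
                )
        write_tsv(pd.DataFrame(score_rows), artifact("scores.tsv"), provenance)

        motif_payload = {
            "tool": f"pepscaffold v{__version__}",
            "config_hash": config.config_hash,
            "seed": config.seed,
            "allele": config.allele,
            "anchor_positions": sorted(anchors.anchor_positions),
            "motif": motif.display,
            "n_binders": len(binders),
        }
        artifact("motif.json").write_text(
            json.dumps(motif_payload, indent=2, sort_keys=True) + "\n"
        )

        log_lines.append(f"wrote {len(designs)} designs")
        artifact("run.log").write_text("\n".join(log_lines) + "\n")
    except Exception:
        for path in artifacts.values():
            path.unlink(missing_ok=True)
        raise

    return RunReport(
        config=config,
        motif_display=motif.display,
        designs=designs,
        out_dir=out_dir,
        artifacts=artifacts,
    )
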