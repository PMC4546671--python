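"""End-to-end orchestration: simulate → filter → assemble → polish → decompose → verify.

Every run writes a machine-readable manifest (inputs, parameters, versions,
seed) next to its artifacts so it can be reproduced exactly.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .assembly import RefinementConfig, assemble_draft, polish_detailed
from .decompose import (MotifDictionary, composition, decompose,
                        decomposition_to_bed, locate_repeat_tract,
                        render_schematic)
from .dna import validate_dna
from .reads import filter_reads, write_filter_audit
from .simulate import (ErrorModel, TruncatedGeometric, build_template,
                       random_flanks, simulate_reads, write_read_metadata,
                       write_reads_fasta)
from .verify import FlankWindows, flank_table_tsv, verify_flanks

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "default_demo_config",
           "run_pipeline", "decompose_fasta", "config_from_file"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# Demo template loosely shaped like an epilepsy-associated expansion:
# the characteristic interrupted 5' lead-in, a long canonical stretch,
# interspersed ATCCT blocks and an ATCCC-dominated 3' end.
_DEMO_BLOCK_SPEC = (
    [["ATTTTCT", 1], ["ATTCT", 1], ["ATATTCT", 1], ["ATTCT", 1],
     ["ATATTCT", 1], ["ATTCT", 1], ["ATTTTCT", 1]]
    + [["ATTCT", 220]]
    + [["ATCCT", 1], ["ATTCT", 3]] * 15
    + [["ATTCT", 60]]
    + [["ATCCC", 250]]
)


@dataclass
class PipelineConfig:
    seed: int = 0
    depth: int = 30
    pass_geometric_p: float = 0.35
    max_passes: int = 12
    p_insertion: float = 0.10
    p_deletion: float = 0.04
    p_substitution: float = 0.01
    flank5_length: int = 832
    flank3_length: int = 1165
    flank_seed: int = 20150821
    block_spec: list = field(default_factory=lambda: [list(x) for x in _DEMO_BLOCK_SPEC])
    min_read_length: int = 50
    min_read_quality: float = 0.75
    rounds: list = field(default_factory=lambda: [[4000, 0.85], [4500, 0.80]])
    max_polish_iterations: int = 3
    end_window5: int = 800
    end_window3: int = 500
    dictionary_path: str = ""

    def error_model(self) -> ErrorModel:
        return ErrorModel(self.p_insertion, self.p_deletion,
                          self.p_substitution, self.seed)

    def dictionary(self) -> MotifDictionary:
        if self.dictionary_path:
            return MotifDictionary.from_json(self.dictionary_path)
        return MotifDictionary.default()


def default_demo_config(seed: int = 0) -> PipelineConfig:
    return PipelineConfig(seed=seed)


def config_from_file(path) -> PipelineConfig:
    """Flat ``key = value`` config; values are parsed as JSON when possible."""
    cfg = PipelineConfig()
    valid = set(asdict(cfg))
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise PipelineError("config", f"line {lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in valid:
            raise PipelineError("config", f"line {lineno}: unknown key {key!r}")
        value = value.strip()
        try:
            parsed = json.loads(value)
        except json.JSONDecodeError:
            parsed = value
        setattr(cfg, key, parsed)
    return cfg


def _versions() -> dict:
    import Bio
    import numba
    import scipy
    return {"tandemtract": __version__, "python": platform.python_version(),
            "numpy": np.__version__, "scipy": scipy.__version__,
            "biopython": Bio.__version__, "numba": numba.__version__}


@dataclass
class PipelineResult:
    outdir: Path
    template_sequence: str
    consensus: str
    tract_interval: tuple
    composition: dict
    verification: list
    manifest: dict


def run_pipeline(config: PipelineConfig, outdir) -> PipelineResult:
    """Run all stages on a simulated read set and write every artifact."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dictionary = config.dictionary()

    # --- simulate ---------------------------------------------------------
    try:
        flank5, flank3 = random_flanks(config.flank5_length,
                                       config.flank3_length, config.flank_seed)
        template = build_template([tuple(x) for x in config.block_spec],
                                  flank5, flank3,
                                  canonical=dictionary.canonical)
        model = config.error_model()
        reads = simulate_reads(
            template, config.depth,
            TruncatedGeometric(config.pass_geometric_p, config.max_passes),
            model)
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc
    write_reads_fasta(reads, outdir / "reads.fasta", seed=config.seed)
    write_read_metadata(reads, outdir / "reads.tsv")
    (outdir / "template.fasta").write_text(
        f">template seed={config.seed}\n{template.sequence}\n")

    # --- filter -----------------------------------------------------------
    audit: list = []
    kept = filter_reads(reads, config.min_read_length, config.min_read_quality,
                        audit=audit)
    write_filter_audit(audit, outdir / "filter_audit.tsv")
    if not kept:
        raise PipelineError("filter", "no reads passed the initial filter")

    # --- assemble + polish ------------------------------------------------
    try:
        draft = assemble_draft(kept)
    except Exception as exc:
        raise PipelineError("assemble", str(exc)) from exc
    try:
        refinement = RefinementConfig(tuple(tuple(r) for r in config.rounds),
                                      config.max_polish_iterations)
        consensus, round_reports = polish_detailed(draft, kept, refinement)
    except Exception as exc:
        raise PipelineError("polish", str(exc)) from exc
    (outdir / "consensus.fasta").write_text(
        f">consensus seed={config.seed}\n{consensus}\n")
    with (outdir / "polish_rounds.tsv").open("w") as fh:
        fh.write("round\tmin_length\tmin_quality\treads_used\t"
                 "edit_distances\tconverged\tskipped\n")
        for r in round_reports:
            fh.write(f"{r.round_index}\t{r.min_length}\t{r.min_quality}\t"
                     f"{r.reads_used}\t{','.join(map(str, r.edit_distances))}\t"
                     f"{r.converged}\t{r.skipped}\n")

    # --- decompose --------------------------------------------------------
    try:
        start, end = locate_repeat_tract(consensus, flank5, flank3)
        decomp = decompose(consensus[start:end], dictionary)
        summary = composition(decomp, dictionary)
    except Exception as exc:
        raise PipelineError("decompose", str(exc)) from exc
    comp_dict = summary.to_dict()
    comp_dict["tract_interval"] = [start, end]
    (outdir / "composition.json").write_text(
        json.dumps(comp_dict, indent=2, sort_keys=True) + "\n")
    (outdir / "blocks.bed").write_text(decomposition_to_bed(decomp, "consensus"))
    (outdir / "schematic.txt").write_text(
        render_schematic(decomp, dictionary) + "\n")

    # --- verify -----------------------------------------------------------
    try:
        rows = verify_flanks(consensus, template.sequence,
                             FlankWindows(flank5, flank3,
                                          config.end_window5, config.end_window3))
    except Exception as exc:
        raise PipelineError("verify", str(exc)) from exc
    flank_table_tsv(rows, outdir / "verification.tsv")

    manifest = {
        "parameters": asdict(config),
        "seed": config.seed,
        "versions": _versions(),
        "inputs": {"template": "simulated", "n_reads": len(reads),
                   "n_reads_filtered": len(kept)},
        "artifacts": sorted(p.name for p in outdir.iterdir()),
        "dictionary": dictionary.to_dict(),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return PipelineResult(outdir, template.sequence, consensus, (start, end),
                          comp_dict, rows, manifest)


def decompose_fasta(fasta_path, dictionary: MotifDictionary | None = None,
                    flank5: str | None = None, flank3: str | None = None,
                    flank5_length: int | None = None,
                    flank3_length: int | None = None) -> list[dict]:
    """Per-record motif composition report for a FASTA file.

    The repeat tract is delimited by aligning ``flank5``/``flank3`` when
    given, by trimming fixed ``flank5_length``/``flank3_length`` when given,
    otherwise the whole record is treated as the tract.
    """
    from Bio import SeqIO

    if dictionary is None:
        dictionary = MotifDictionary.default()
    path = Path(fasta_path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA not found: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    reports = []
    for rec in records:
        seq = validate_dna(str(rec.seq), name=f"record {rec.id}")
        if flank5 and flank3:
            start, end = locate_repeat_tract(seq, flank5, flank3)
        elif flank5_length is not None and flank3_length is not None:
            start, end = flank5_length, len(seq) - flank3_length
            if end <= start:
                raise ValueError(f"record {rec.id}: flank lengths exceed record")
        else:
            start, end = 0, len(seq)
        decomp = decompose(seq[start:end], dictionary)
        summary = composition(decomp, dictionary).to_dict()
        summary["record_id"] = rec.id
        summary["record_length"] = len(seq)
        summary["tract_interval"] = [start, end]
        reports.append(summary)
    return reports
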