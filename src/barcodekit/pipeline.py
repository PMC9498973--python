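"""One-command end-to-end barcoding analysis.

From a FASTA + metadata pair the pipeline emits, in order: per-region
composition (regions.tsv), the haplotype table (haplotypes.tsv), the
variable-site report and diagnostic key (sites.tsv, key.json), distance
summaries (within.tsv, between.tsv, matrix.tsv), bootstrapped trees for
the full marker and both spacer regions (tree_<region>.nwk), a per-region
species-monophyly table (monophyly.tsv) and a JSON run log.  Every output
is a pure function of (inputs, config, seed); rerunning with the same seed
reproduces the files byte for byte.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import distances as dist
from . import haplotypes as haps
from . import msa
from . import phylo
from . import regions as reg
from . import seqio
from . import sites as sitesmod

REGION_CHOICES = ("its", "its1", "its2")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    fasta: str | Path
    metadata: str | Path
    out_dir: str | Path
    seed: int = 0
    prealigned: bool = False
    boundaries: reg.RegionBoundaries | None = None  # None -> infer 5.8S
    bootstrap_reps: int = 1000
    method: str = "nj"  # tree builder: "nj" or "ml"
    outgroup: str | None = None  # None -> taken from metadata flags
    regions: tuple[str, ...] = REGION_CHOICES

    def __post_init__(self) -> None:
        if self.bootstrap_reps < 0:
            raise ValueError("bootstrap_reps must be >= 0")
        if self.method not in ("nj", "ml"):
            raise ValueError(f"unknown tree method {self.method!r}")
        for r in self.regions:
            if r not in REGION_CHOICES:
                raise ValueError(f"unknown region {r!r}")


@dataclass
class RunResult:
    out_dir: Path
    alignment_length: int
    n_samples: int
    n_haplotypes: int
    n_variable_sites: int
    diagnostic_key: sitesmod.DiagnosticKey
    gap_report: dist.BarcodeGapReport
    monophyly: dict[str, dict[str, bool]]  # region -> species -> bool
    files: list[str] = field(default_factory=list)


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format="%.2f",
                 lineterminator="\n")


def run_full_analysis(config: RunConfig) -> RunResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        stage = "read"
        records = seqio.read_fasta(config.fasta)
        metadata = seqio.read_metadata(config.metadata)
        records = seqio.attach_metadata(records, metadata)
        outgroup = config.outgroup or seqio.outgroup_species(metadata)

        stage = "align"
        alignment = msa.align(records, prealigned=config.prealigned)

        stage = "haplotypes"
        table = haps.collapse_haplotypes(alignment, metadata)
        _write_tsv(haps.haplotype_table_frame(table), out / "haplotypes.tsv")
        written.append(out / "haplotypes.tsv")
        hap_aln = haps.representative_alignment(table)
        hap_species = {h.hap_id: h.species for h in table.haplotypes}
        hap_meta = [
            seqio.SampleMetadata(
                sample_id=h.hap_id, species=h.species,
                is_outgroup=(h.species == outgroup),
            )
            for h in table.haplotypes
        ]

        stage = "regions"
        boundaries = config.boundaries or reg.infer_58s_window(hap_aln)
        stats = reg.region_stats(hap_aln, boundaries)
        _write_tsv(reg.format_region_table(stats), out / "regions.tsv")
        written.append(out / "regions.tsv")

        stage = "sites"
        report = sitesmod.classify_sites(hap_aln, hap_meta)
        _write_tsv(report, out / "sites.tsv")
        written.append(out / "sites.tsv")
        key = sitesmod.diagnostic_sites(hap_aln, hap_meta)
        (out / "key.json").write_text(
            json.dumps(sitesmod.key_to_dict(key), indent=1) + "\n"
        )
        written.append(out / "key.json")
        n_variable = sitesmod.variable_site_count(report)

        stage = "distances"
        ingroup_ids = [h.hap_id for h in table.haplotypes
                       if h.species != outgroup]
        matrix = dist.pairwise_matrix(hap_aln.subset(ingroup_ids))
        _write_tsv(matrix.to_frame(), out / "matrix.tsv", index=True)
        written.append(out / "matrix.tsv")
        summary = dist.group_means(matrix, hap_species)
        within_tbl, between_tbl = dist.summary_tables(summary)
        _write_tsv(within_tbl, out / "within.tsv")
        _write_tsv(between_tbl, out / "between.tsv", index=True)
        written.extend([out / "within.tsv", out / "between.tsv"])
        gap_report = dist.barcode_gap(summary)

        stage = "trees"
        spans = {
            "its": (1, hap_aln.length),
            "its1": boundaries.its1,
            "its2": boundaries.its2,
        }
        monophyly: dict[str, dict[str, bool]] = {}
        for region in config.regions:
            lo, hi = spans[region]
            if hi - lo + 1 < 10:  # degenerate spacer span: no usable signal
                monophyly[region] = {}
                continue
            sub = hap_aln.slice_columns(lo, hi)
            if config.bootstrap_reps > 0:
                boot = phylo.bootstrap_support(
                    sub, builder=config.method,
                    reps=config.bootstrap_reps, seed=config.seed,
                )
                tree = boot.tree
            else:
                dm = dist.pairwise_matrix(sub)
                tree = (phylo.neighbor_joining(dm) if config.method == "nj"
                        else phylo.ml_search(sub).tree)
            rooted, mono = phylo.root_and_monophyly(
                tree, hap_species, outgroup
            )
            monophyly[region] = mono
            path = out / f"tree_{region}.nwk"
            path.write_text(phylo.write_newick(rooted) + "\n")
            written.append(path)
        mono_rows = [
            {"region": region, "species": sp, "monophyletic": int(flag)}
            for region, table_ in monophyly.items()
            for sp, flag in sorted(table_.items())
        ]
        _write_tsv(pd.DataFrame(mono_rows), out / "monophyly.tsv")
        written.append(out / "monophyly.tsv")

        stage = "log"
        n_ingroup = sum(1 for m in metadata if not m.is_outgroup)
        log = {
            "seed": config.seed,
            "prealigned": config.prealigned,
            "method": config.method,
            "bootstrap_reps": config.bootstrap_reps,
            "outgroup": outgroup,
            "n_samples_ingroup": n_ingroup,
            "n_haplotypes_ingroup": sum(
                1 for h in table.haplotypes if h.species != outgroup
            ),
            "n_variable_sites": n_variable,
            "alignment_length": alignment.length,
            "boundaries": {
                "its1": list(boundaries.its1),
                "58s": list(boundaries.r58s),
                "its2": list(boundaries.its2),
            },
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=1) + "\n")
        written.append(out / "run_log.json")
    except Exception as exc:  # keep partial outputs, but mark them
        for path in written:
            if path.exists():
                path.rename(path.with_suffix(path.suffix + ".partial"))
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc

    ingroup_species = sorted(
        {m.species for m in metadata if not m.is_outgroup}
    )
    n_hap_ingroup = sum(
        1 for h in table.haplotypes if h.species != outgroup
    )
    return RunResult(
        out_dir=out,
        alignment_length=alignment.length,
        n_samples=sum(1 for m in metadata if not m.is_outgroup),
        n_haplotypes=n_hap_ingroup,
        n_variable_sites=n_variable,
        diagnostic_key=key,
        gap_report=gap_report,
        monophyly=monophyly,
        files=[str(p) for p in written],
    )
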