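"""End-to-end orchestration: config, stages, machine-readable reports.

``run_all`` executes the full analysis on one family — regions, motif scan,
frequencies, trends, class ratios, bootstrap divergence, mutation overlap —
and writes each result as TSV/JSON into the output directory together with
a run manifest recording inputs and seeds.  Stages whose inputs are absent
(e.g. no mutation catalog) are skipped and noted in the manifest.  Outputs
are deterministic for a fixed config, so a rerun reproduces them
byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .conservation import bootstrap_divergence, divergence_table
from .errors import InputError, MemevoError
from .frequencies import (
    REGION_CLASSES,
    class_ratios,
    classify_all_trends,
    region_class_positions,
    region_frequencies,
)
from .motifs import MOTIF_KINDS, localize_motifs, motif_region_coordinates, scan_all
from .mutations import annotate_catalog, overlap_summary, read_mutation_catalog, region_mutation_rates
from .seq_io import attach_metadata, build_column_map, read_fasta, read_metadata
from .topology import derive_lwi_regions, read_topology, regions_to_frame

logger = logging.getLogger("memevo")

COORD_NOTE = "# coordinates: 1-based inclusive\n"


@dataclass
class RunConfig:
    alignment: str
    metadata: str
    topology: str
    reference_id: str
    out_dir: str
    mutations: str | None = None
    mutation_column: str | None = None
    motif_kinds: tuple[str, ...] = MOTIF_KINDS
    collapse: str = "spans"
    carc_central: str = "Y"
    flank_width: int = 5
    n_replicates: int = 1000
    bootstrap_seed: int = 1
    trend_alpha: float = 0.05
    trend_cv_max: float = 0.5
    natural_tol: float = 0.20

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        path = Path(path)
        data = (
            yaml.safe_load(path.read_text())
            if path.suffix.lower() in {".yml", ".yaml"}
            else json.loads(path.read_text())
        )
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "motif_kinds" in data:
            data["motif_kinds"] = tuple(data["motif_kinds"])
        return cls(**data)

    def validate(self) -> None:
        for name in ("alignment", "metadata", "topology"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise InputError(f"{name} file not found: {p}")
        if self.mutations is not None and not Path(self.mutations).exists():
            raise InputError(f"mutations file not found: {self.mutations}")


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(COORD_NOTE)
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n", float_format="%.6g")


def run_all(config: RunConfig) -> dict:
    """Run every applicable stage; returns the manifest dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "memevo",
        "version": __version__,
        "inputs": {
            "alignment": str(config.alignment),
            "metadata": str(config.metadata),
            "topology": str(config.topology),
            "mutations": str(config.mutations) if config.mutations else None,
        },
        "parameters": {
            "reference_id": config.reference_id,
            "motif_kinds": list(config.motif_kinds),
            "collapse": config.collapse,
            "carc_central": config.carc_central,
            "flank_width": config.flank_width,
            "n_replicates": config.n_replicates,
            "bootstrap_seed": config.bootstrap_seed,
            "trend_alpha": config.trend_alpha,
            "trend_cv_max": config.trend_cv_max,
            "natural_tol": config.natural_tol,
        },
        "stages": {},
        "skipped": [],
    }

    def stage(name: str):
        def wrap(fn):
            try:
                fn()
                manifest["stages"][name] = "ok"
            except MemevoError:
                manifest["stages"][name] = "failed"
                (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
                raise MemevoError(f"stage {name!r} failed") from None
            return fn
        return wrap

    aln = read_fasta(config.alignment, aligned=True, reference_id=config.reference_id)
    meta = read_metadata(config.metadata)
    attach_metadata(aln.records, meta)
    topo = read_topology(config.topology)
    cmap = build_column_map(aln, config.reference_id)
    reference = aln.reference()
    ref_ungapped = type(reference)(
        id=reference.id, sequence=reference.ungapped(),
        species=reference.species, clade=reference.clade,
    )

    regions = derive_lwi_regions(topo, flank_width=config.flank_width, allow_truncated=True)

    @stage("regions")
    def _regions():
        _write_tsv(regions_to_frame(regions), out / "regions.tsv")

    motifs = localize_motifs(
        scan_all(ref_ungapped, kinds=config.motif_kinds, collapse=config.collapse,
                 carc_central=config.carc_central),
        topo, regions,
    )

    @stage("motifs")
    def _motifs():
        _write_tsv(motif_region_coordinates(motifs), out / "motifs.tsv")

    freqs = region_frequencies(aln, regions, topo, cmap)

    @stage("frequencies")
    def _freqs():
        _write_tsv(freqs, out / "frequencies.tsv")

    @stage("trends")
    def _trends():
        trends = classify_all_trends(
            freqs,
            alpha=config.trend_alpha,
            cv_max=config.trend_cv_max,
            natural_tol=config.natural_tol,
        )
        _write_tsv(trends, out / "trends.tsv")

    @stage("ratios")
    def _ratios():
        _write_tsv(class_ratios(freqs), out / "ratios.tsv")

    @stage("divergence")
    def _divergence():
        class_pos = region_class_positions(regions, topo)
        profiles = []
        targets = [(r.label, list(r.positions)) for r in regions]
        targets += [(name, sorted(set(class_pos[name])))
                    for name in ("inner_LWI", "outer_LWI", "total_LWI", "N_LWI", "C_LWI", "TM", "full_length")]
        for label, positions in targets:
            cols = cmap.columns_for(positions)
            profiles.append(
                bootstrap_divergence(
                    aln, cols, n_replicates=config.n_replicates,
                    seed=config.bootstrap_seed, region_label=label,
                )
            )
        _write_tsv(divergence_table(profiles), out / "divergence.tsv")

    if config.mutations:
        @stage("mutations")
        def _mutations():
            muts = read_mutation_catalog(config.mutations, column=config.mutation_column)
            summary = overlap_summary(muts, regions, motifs)
            rates = region_mutation_rates(muts, regions, topo.protein_length)
            payload = {"overlap": summary.as_dict(), "rates": rates}
            (out / "mutation_overlap.json").write_text(json.dumps(payload, indent=2) + "\n")
            _write_tsv(annotate_catalog(muts, regions, motifs), out / "mutations_annotated.tsv")
    else:
        manifest["skipped"].append("mutations")
        logger.info("no mutation catalog given; overlap stage skipped")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
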