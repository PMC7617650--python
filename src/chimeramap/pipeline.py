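"""End-to-end orchestration: simulate -> preprocess -> call -> analyse.

A :class:`PipelineConfig` pins every tunable (bin sizes, the TopDom-style
window, the site radius/step, enrichment thresholds, seeds); defaults
are the study-standard values. :func:`run_pipeline` executes the stages
deterministically and writes each stage's outputs plus a manifest with
parameters and SHA-256 hashes of every file produced.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import contacts, diff, domains, io, sites, synth
from .calling import call_chimeras

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("chimeramap")


@dataclass
class PipelineConfig:
    """Validated pipeline parameters; defaults are the standard settings
    (100-nt correlation bins, 10-nt analysis bins, window 30, 50-nt site
    radius and permutation step, p 0.05, fold 1.25)."""

    outdir: str = "pipeline_out"
    seed: int = 0
    # synthetic library
    transcript_length: int = 5000
    gc: float = 0.4
    n_chimeras: int = 20000
    n_replicates: int = 3
    background_rate: float = 0.2
    stems: list[dict[str, Any]] = field(default_factory=list)
    # preprocessing / calling
    umi_len: int = 6
    min_len: int = 10
    kmer: int = 12
    min_arm: int = 15
    # analysis
    bin_size_correlation: int = 100
    bin_size: int = 10
    window: int = 30
    radius: int = 50
    step: int = 50
    p_threshold: float = 0.05
    fold_threshold: float = 1.25
    site_centers: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        checks = [
            (self.transcript_length >= 1, "transcript_length must be >= 1"),
            (0 <= self.gc <= 1, "gc must be in [0, 1]"),
            (self.n_chimeras >= 0, "n_chimeras must be >= 0"),
            (self.n_replicates >= 1, "n_replicates must be >= 1"),
            (0 <= self.background_rate <= 1, "background_rate must be in [0, 1]"),
            (self.bin_size >= 1 and self.bin_size_correlation >= 1, "bin sizes must be >= 1"),
            (self.window >= 1, "window must be >= 1"),
            (self.radius >= 1 and self.step >= 1, "radius and step must be >= 1"),
            (0 < self.p_threshold < 1, "p_threshold must be in (0, 1)"),
            (self.fold_threshold > 0, "fold_threshold must be positive"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _build_model(cfg: PipelineConfig) -> synth.StructureModel:
    transcript = synth.random_transcript(cfg.transcript_length, cfg.gc, seed=cfg.seed)
    stems = [
        synth.StemSpec(
            strand5=tuple(s["strand5"]), strand3=tuple(s["strand3"]),
            weight=float(s.get("weight", 1.0)),
        )
        for s in cfg.stems
    ]
    return synth.StructureModel(
        transcript=transcript, stems=stems, background_rate=cfg.background_rate
    )


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Run simulate -> reads -> call -> contact maps -> domains -> site
    tests; returns a result bundle and writes everything under
    ``cfg.outdir`` with a manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    model = _build_model(cfg)
    reference = {model.transcript.id: model.transcript.dna()}
    io.write_fasta(reference, out / "reference.fa")

    stage = "simulate"
    try:
        replicates = synth.simulate_replicates(
            model, cfg.n_chimeras, cfg.n_replicates, seed=cfg.seed
        )
        for r, recs in enumerate(replicates):
            io.write_hyb(recs, out / f"rep{r}.hyb.tsv")

        stage = "callchim"
        called: list[list[io.ChimeraRecord]] = []
        for r, recs in enumerate(replicates):
            reads = synth.chimeras_to_reads(recs, model.transcript, seed=cfg.seed + r)
            result = call_chimeras(reads, reference, k=cfg.kmer, min_arm=cfg.min_arm)
            called.append(result.chimeras)
            log.info("replicate %d: %d chimeric, %d single, %d unmapped",
                     r, result.n_chimeric, result.n_single, result.n_unmapped)

        stage = "cmap"
        maps = [
            contacts.build_contact_map(recs, model.transcript, cfg.bin_size)
            for recs in called
        ]
        cor_maps = [
            contacts.build_contact_map(recs, model.transcript, cfg.bin_size_correlation)
            for recs in called
        ]
        corr = np.ones((len(maps), len(maps)))
        for i in range(len(maps)):
            for j in range(i + 1, len(maps)):
                r_ij, _ = contacts.replicate_correlation(cor_maps[i], cor_maps[j])
                corr[i, j] = corr[j, i] = r_ij
        np.savetxt(out / "replicate_correlation.tsv", corr, fmt="%.6f", delimiter="\t")
        pooled = contacts.ContactMap(
            transcript_id=maps[0].transcript_id, bin_size=cfg.bin_size,
            counts=sum(m.counts for m in maps),
            total_mapped=sum(m.total_mapped for m in maps), length=maps[0].length,
        )
        pooled.to_sparse_tsv(out / "contact_map.sparse.tsv")

        stage = "domains"
        domain_set = domains.call_domains(pooled, w=cfg.window, p_cutoff=cfg.p_threshold)
        domain_set.to_bed(out / "domains.bed.tsv", pooled.transcript_id)

        stage = "diff"
        table = diff.window_counts(
            {f"rep{r}": recs for r, recs in enumerate(called)},
            model.transcript, cfg.bin_size,
        )
        table.to_csv(out / "window_counts.tsv", sep="\t")

        stage = "clustersites"
        site_results = []
        if len(cfg.site_centers) >= 2:
            site_list = [
                sites.SiteCluster(f"site{i}", c, cfg.radius)
                for i, c in enumerate(cfg.site_centers)
            ]
            site_results = sites.circular_permutation_test(
                called, site_list, cfg.transcript_length, step=cfg.step
            )
            with open(out / "site_pairs.tsv", "w") as fh:
                fh.write("site_a\tsite_b\tobserved_mean\tpermuted_mean\tt\tp\tpadj\n")
                for res in site_results:
                    fh.write(
                        f"{res.pair[0]}\t{res.pair[1]}\t{res.mean_observed:g}\t"
                        f"{res.mean_permuted:g}\t{res.t_statistic:g}\t"
                        f"{res.p_value:g}\t{res.p_adjusted:g}\n"
                    )
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest = {
        "parameters": asdict(cfg),
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "model": model,
        "called": called,
        "maps": maps,
        "pooled_map": pooled,
        "domains": domain_set,
        "window_counts": table,
        "site_tests": site_results,
        "replicate_correlation": corr,
        "manifest": manifest,
    }
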