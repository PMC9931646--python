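"""End-to-end orchestration: read -> filter -> score -> call -> summarize.

`run_pipeline` drives the whole workflow from a :class:`RunConfig`,
producing per-condition interaction tables, optional gene x TF affinity
matrices, and a run manifest with input checksums so results are
reproducible and attributable. Outputs are deterministic for a given
config; the worker count never changes results, only wall time.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .affinity import (
    background_composition,
    gene_tf_matrix,
    pfm_to_energy,
    region_affinity_matrix,
    region_sequences,
)
from .contacts import (
    DEFAULT_PSEUDOCOUNT,
    DEFAULT_RESOLUTION,
    DistanceContactModel,
    read_contact_triples,
)
from .io import (
    filter_excluded_regions,
    load_activity,
    read_gene_annotation,
    read_pfms,
    read_regions,
)
from .scoring import ScoringConfig, call_interactions, score_all

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("gabc.pipeline")

#: Sentinel for the contacts path selecting the inverse-distance fallback.
DISTANCE_MODEL = "distance-model"


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Paths may be strings or Path objects; ``contacts`` is either a triplet
    file or the literal ``"distance-model"`` to use the inverse-distance
    estimate. ``mode`` selects the interaction score ("abc" or "gabc");
    ``summarize`` selects the affinity regime ("window", "abc" or "gabc").
    Motifs and genome are optional — without them the affinity stage is
    skipped with a notice.
    """

    regions: str
    annotation: str
    activity: str
    contacts: str = DISTANCE_MODEL
    motifs: str | None = None
    genome: str | None = None
    exclusion: str | None = None
    outdir: str = "gabc_out"
    mode: str = "gabc"
    summarize: str = "gabc"
    window: float = 5_000_000
    cutoff: float = 0.02
    resolution: int = DEFAULT_RESOLUTION
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    normalize: str = "none"
    tss_proximal_bp: float = 2500
    decay_d0: float = 5000.0
    seed: int = 0
    n_workers: int = 1
    gzip_output: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("abc", "gabc"):
            raise ValueError("mode must be 'abc' or 'gabc'")
        if self.summarize not in ("window", "abc", "gabc"):
            raise ValueError("summarize must be window/abc/gabc")

    def validate_paths(self) -> None:
        required = {"regions": self.regions, "annotation": self.annotation,
                    "activity": self.activity}
        if self.contacts != DISTANCE_MODEL:
            required["contacts"] = self.contacts
        for name in ("motifs", "genome", "exclusion"):
            val = getattr(self, name)
            if val is not None:
                required[name] = val
        missing = [n for n, p in required.items() if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")

    def scoring_config(self, mode: str | None = None) -> ScoringConfig:
        m = mode or self.mode
        return ScoringConfig(
            window=self.window,
            cutoff=self.cutoff,
            use_adapted_activity=(m == "gabc"),
            use_all_tss=(m == "gabc"),
            tss_proximal_bp=self.tss_proximal_bp,
            decay_d0=self.decay_d0,
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Read a flat key-value config file (``key = value`` per line)."""
        kwargs: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if value.lower() in ("true", "false"):
                kwargs[key] = value.lower() == "true"
            elif key in ("window", "cutoff", "pseudocount",
                         "tss_proximal_bp", "decay_d0"):
                kwargs[key] = float(value)
            elif key in ("resolution", "seed", "n_workers"):
                kwargs[key] = int(value)
            elif value.lower() == "none":
                kwargs[key] = None
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, existence_check: bool = False) -> Path:
    """Run the full workflow and return the output directory.

    Stages: read inputs -> exclusion filter -> activity normalization ->
    batched scoring over all conditions (ABC and gABC columns) ->
    interaction calling at the configured cutoff -> optional TF affinity
    summarization -> tables + manifest. With ``existence_check=True`` only
    input validation runs (dry run).
    """
    config.validate_paths()
    if existence_check:
        logger.info("existence check passed; dry run requested")
        return Path(config.outdir)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    regions = read_regions(config.regions)
    genes = read_gene_annotation(config.annotation)
    logger.info("read %d regions, %d genes", len(regions), len(genes))

    enhancers = load_activity(config.activity, regions,
                              normalize=config.normalize)
    n_excluded = 0
    if config.exclusion is not None:
        exclusion = read_regions(config.exclusion)
        enhancers, n_excluded = filter_excluded_regions(enhancers, exclusion)
    logger.info("excluded %d region(s); %d candidates remain",
                n_excluded, len(enhancers))

    if config.contacts == DISTANCE_MODEL:
        contacts = DistanceContactModel(min_distance=config.resolution)
    else:
        contacts = read_contact_triples(
            config.contacts, config.resolution,
            pseudocount=config.pseudocount,
        )

    conditions = sorted(enhancers[0].activity) if enhancers else []
    abc = score_all(enhancers, genes, contacts,
                    config.scoring_config("abc"), conditions,
                    n_workers=config.n_workers)
    gabc = score_all(enhancers, genes, contacts,
                     config.scoring_config("gabc"), conditions,
                     n_workers=config.n_workers)
    primary = gabc if config.mode == "gabc" else abc
    merged = _merge_score_tables(abc, gabc, primary_mode=config.mode)
    called = call_interactions(primary, config.cutoff)
    for cond in conditions:
        logger.info(
            "condition %s: %d interactions called at cutoff %g",
            cond, int((called["condition"] == cond).sum()), config.cutoff,
        )

    suffix = ".tsv.gz" if config.gzip_output else ".tsv"
    for cond in conditions:
        sub = merged[merged["condition"] == cond].drop(columns=["condition"])
        sub.to_csv(outdir / f"interactions_{cond}{suffix}",
                   sep="\t", index=False)

    affinity_done = False
    if config.motifs is not None and config.genome is not None:
        motifs = read_pfms(config.motifs)
        kept_regions = [e.region for e in enhancers]
        seqs = region_sequences(config.genome, kept_regions)
        background = background_composition(seqs.values())
        energies = [pfm_to_energy(m, background) for m in motifs]
        aff = region_affinity_matrix(seqs, energies)
        widths = {m.tf_name: m.width for m in motifs}
        lengths = {r.region_id: r.length for r in kept_regions}
        scfg = config.scoring_config()
        for cond in conditions:
            mat = gene_tf_matrix(primary, cond, aff, widths,
                                 config.summarize, scfg, lengths)
            mat.to_csv(outdir / f"gene_tf_{cond}{suffix}", sep="\t")
        affinity_done = True
        logger.info("affinity stage: %d TFs x %d conditions",
                    len(motifs), len(conditions))
    else:
        logger.info("affinity stage skipped (motifs/genome not provided)")

    checksums = {}
    for name in ("regions", "annotation", "activity", "contacts",
                 "motifs", "genome", "exclusion"):
        val = getattr(config, name)
        if val is not None and val != DISTANCE_MODEL and Path(val).exists():
            checksums[name] = _sha256(val)
    cfg_dict = asdict(config)
    manifest = {
        "version": __version__,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "input_checksums": checksums,
        "n_regions": len(regions),
        "n_excluded": n_excluded,
        "n_genes": len(genes),
        "conditions": conditions,
        "n_called": {
            cond: int((called["condition"] == cond).sum())
            for cond in conditions
        },
        "affinity_stage": affinity_done,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return outdir


def _merge_score_tables(abc: pd.DataFrame, gabc: pd.DataFrame,
                        primary_mode: str) -> pd.DataFrame:
    """Combine ABC and gABC runs into one table with both score columns.

    Geometry columns (contact, distance, adapted activity) come from the
    primary mode's run; candidate pairs present in only one run keep NaN
    in the other score column (the 5'-TSS and all-TSS windows can differ).
    """
    primary = (gabc if primary_mode == "gabc" else abc).rename(
        columns={"score": f"score_{primary_mode}"}
    )
    other_mode = "abc" if primary_mode == "gabc" else "gabc"
    other = (abc if primary_mode == "gabc" else gabc)[
        ["region_id", "gene_id", "condition", "score"]
    ].rename(columns={"score": f"score_{other_mode}"})
    merged = primary.merge(
        other, on=["region_id", "gene_id", "condition"], how="left"
    )
    cols = ["region_id", "gene_id", "condition", "activity",
            "adapted_activity", "contact", "score_abc", "score_gabc",
            "distance"]
    return merged[cols]
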