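"""End-to-end pipeline and reporting.

``run_pipeline`` ties the stages together: read sequences and sites
(or generate synthetic ones), extract windows, cluster the positives
into motif subgroups, balance the negatives, train single and/or
MDD-clustered models, cross-validate, and write every artifact (tree
JSON, position-frequency matrices, model bundle, metrics report,
predictions) stamped with the tool version, a hash of the effective
configuration, and the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from glycmotif.classifier import (
    EvalMetrics,
    SVMParams,
    cross_validate,
    predict,
    train_mdd_clustered,
    train_single,
)
from glycmotif.encoders import (
    ASANormalizer,
    EncoderArtifacts,
    build_pwm,
    read_asa_table,
    read_pssm,
)
from glycmotif.mdd import MDDConfig, export_pfm, mdd_cluster, save_tree
from glycmotif.sampling import SamplingConfig, kmeans_subsample
from glycmotif.seqdata import (
    WindowConfig,
    extract_fragments,
    protein_index,
    read_fasta,
    read_site_table,
    validate_sites,
    write_fragments,
)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """Declarative pipeline configuration (CLI flags override fields)."""

    fasta: str = ""
    sites: str = ""
    asa: str = ""
    pssm_dir: str = ""
    out_dir: str = "glycmotif_run"
    scheme: str = "binary"
    mode: str = "mdd_clustered"
    n: int = 5
    chi2_threshold: float = 34.3
    min_cluster_size: int = 150
    svm_c: float = 8.0
    svm_gamma: float = 2.0**-6
    cv_folds: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # output location does not affect results
        canonical = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]

    def window(self) -> WindowConfig:
        return WindowConfig(n=self.n)

    def mdd(self) -> MDDConfig:
        return MDDConfig(
            chi2_threshold=self.chi2_threshold,
            min_cluster_size=self.min_cluster_size,
            window=self.window(),
        )


def _provenance(cfg: RunConfig) -> dict:
    return {"version": __version__, "config_hash": cfg.config_hash(), "seed": cfg.seed}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute extract -> cluster -> sample -> train -> cv; write artifacts.

    Returns a dict of artifact paths plus the computed metrics.
    Deterministic: the same configuration (hash) reproduces identical
    artifacts byte for byte.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = _provenance(cfg)
    (out / "config.json").write_text(
        json.dumps({**prov, "config": asdict(cfg)}, indent=1, sort_keys=True) + "\n"
    )

    # --- extract ------------------------------------------------------
    proteins = protein_index(read_fasta(cfg.fasta))
    sites, rejects = validate_sites(read_site_table(cfg.sites), proteins)
    if rejects:
        logger.warning("stage extract: %d rejected site rows", len(rejects))
    window = cfg.window()
    pos_sites = [s for s in sites if s.label == "positive"]
    neg_sites = [s for s in sites if s.label == "negative"]
    pos_frags = extract_fragments(pos_sites, proteins, window)
    neg_frags = extract_fragments(neg_sites, proteins, window)
    write_fragments(pos_frags + neg_frags, out / "fragments.tsv")

    # --- cluster ------------------------------------------------------
    mdd_cfg = cfg.mdd()
    tree = mdd_cluster(pos_frags, mdd_cfg)
    save_tree(tree, out / "tree.json", mdd_cfg.scheme)
    for leaf in tree.leaves():
        export_pfm(leaf, window).to_tsv(out / f"pfm_leaf{leaf.leaf_id}.tsv")

    # --- sample -------------------------------------------------------
    negs = kmeans_subsample(
        neg_frags, SamplingConfig(k=min(len(pos_frags), len(neg_frags)), seed=cfg.seed)
    )

    # --- encoder artifacts -------------------------------------------
    artifacts = EncoderArtifacts(window=window)
    artifacts.pwm = build_pwm(pos_frags, window)
    if cfg.asa:
        artifacts.asa_table = read_asa_table(cfg.asa)
        artifacts.asa_normalizer = ASANormalizer.fit(artifacts.asa_table.values())
    if cfg.pssm_dir:
        for path in sorted(Path(cfg.pssm_dir).glob("*.pssm")):
            artifacts.profiles[path.stem] = read_pssm(path, path.stem)

    # --- train --------------------------------------------------------
    params = SVMParams(C=cfg.svm_c, gamma=cfg.svm_gamma)
    if cfg.mode == "single":
        bundle = train_single(
            pos_frags, negs, cfg.scheme, params, artifacts, proteins, cfg.seed
        )
    else:
        bundle = train_mdd_clustered(
            pos_frags, negs, mdd_cfg, cfg.scheme, params,
            artifacts=artifacts, proteins=proteins, seed=cfg.seed,
        )
    bundle_path = out / "model.joblib"
    bundle.save(bundle_path)

    # --- cross-validate ----------------------------------------------
    metrics = cross_validate(
        pos_frags, negs, k=cfg.cv_folds, scheme=cfg.scheme, mode=cfg.mode,
        mdd_cfg=mdd_cfg, params=params, artifacts=artifacts,
        proteins=proteins, seed=cfg.seed,
    )
    text, payload = report_metrics(metrics, provenance=prov)
    (out / "metrics.json").write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    (out / "metrics.txt").write_text(text + "\n")

    # --- predict on all training proteins ----------------------------
    rows = predict(bundle, proteins, window=window)
    with open(out / "predictions.tsv", "w") as fh:
        fh.write("#protein_id\tposition\tresidue\tprobability\tlabel\tleaf_id\tmotif_tag\n")
        for r in rows:
            fh.write(
                f"{r['protein_id']}\t{r['position']}\t{r['residue']}\t"
                f"{r['probability']:.6f}\t{r['label']}\t"
                f"{r.get('leaf_id', '')}\t{r.get('motif_tag', '')}\n"
            )

    return {
        "out_dir": str(out),
        "tree": str(out / "tree.json"),
        "bundle": str(bundle_path),
        "metrics": metrics,
        "metrics_json": str(out / "metrics.json"),
        "predictions": str(out / "predictions.tsv"),
    }


def report_metrics(
    metrics: EvalMetrics, style: str = "table", provenance: dict | None = None
) -> tuple[str, dict]:
    """Render metrics as a human table plus a machine payload.

    The table shows the conventional 2-decimal presentation; the JSON
    payload keeps full-precision floats and the confusion counts.
    """
    header = "Sn Sp Acc MCC"
    text = f"{header}\n{metrics.format_row()}"
    payload = {"metrics": metrics.to_dict()}
    if provenance:
        payload.update(provenance)
    return text, payload
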