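"""End-to-end orchestration of the two study contrasts.

A *manifest* (TSV: subject_id, group, condition, ts_path, motion_path)
drives all file I/O, so no metadata is encoded in filenames.  A run
executes preprocess -> connectivity -> difference network + degree ->
NBS (one directional run per sign) -> classification, writes every
intermediate under a fixed layout, and emits a machine-readable
``report.json`` plus a human-readable ``report.md``.  Runs are fully
deterministic given the config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as clf
from . import connectivity as conn
from . import nbs as nbsmod
from . import preprocess as prep
from .errors import ManifestError

__all__ = ["AnalysisConfig", "RunReport", "read_manifest", "run_contrast", "write_report"]

log = logging.getLogger("connectonet")

SCHEMA_VERSION = "1.0"
_MANIFEST_COLUMNS = ["subject_id", "group", "condition", "ts_path", "motion_path"]


@dataclass
class AnalysisConfig:
    """Everything one contrast needs, serialisable and echoed into outputs."""

    contrast: str  # "acute_paired" | "chronic_unpaired"
    data_dir: str
    out_dir: str
    tr_seconds: float = 2.0
    scrub: bool = False
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    use_motion_regressors: bool = True
    diff_p_threshold: float = 0.05
    nbs_threshold_p: float = 0.001
    nbs_permutations: int = 5000
    nbs_alpha: float = 0.05
    nbs_signs: tuple[str, ...] = ("positive", "negative")
    classify_kernels: tuple[str, ...] = clf.DEFAULT_KERNELS
    classify_C_grid: tuple[float, ...] = clf.DEFAULT_C_GRID
    classify_p_threshold: float = 0.05
    classify_permutations: int = 0  # 0 skips the permutation test
    save_matrices: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contrast not in ("acute_paired", "chronic_unpaired"):
            raise ValueError(f"unknown contrast {self.contrast!r}")
        self.nbs_signs = tuple(self.nbs_signs)
        self.classify_kernels = tuple(self.classify_kernels)
        self.classify_C_grid = tuple(float(c) for c in self.classify_C_grid)

    @property
    def design(self) -> str:
        return "paired" if self.contrast == "acute_paired" else "unpaired"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        return cls(**d)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-stage summaries; every number is recomputable from intermediates."""

    schema_version: str
    config: dict
    config_hash: str
    software_version: str
    stages: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate the subject manifest."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # noqa: BLE001
        raise ManifestError(f"cannot read manifest {path}: {exc}") from exc
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest missing column(s): {', '.join(missing)}")
    if df[_MANIFEST_COLUMNS].isna().any().any():
        raise ManifestError("manifest contains empty cells")
    dup = df.duplicated(subset=["subject_id", "condition"])
    if dup.any():
        ids = df.loc[dup, "subject_id"].tolist()
        raise ManifestError(f"duplicate subject/condition rows: {ids}")
    base = path.parent
    for _, row in df.iterrows():
        for col in ("ts_path", "motion_path"):
            f = base / row[col]
            if not f.exists():
                raise ManifestError(f"missing file for {row['subject_id']}: {f}")
    return df


def _check_paired(manifest: pd.DataFrame) -> None:
    counts = manifest.groupby("subject_id")["condition"].nunique()
    bad = counts[counts != 2]
    if len(bad):
        raise ManifestError(
            f"paired contrast needs exactly two conditions per subject; "
            f"offending subject(s): {', '.join(bad.index.tolist())}"
        )


def _load_and_clean(
    manifest: pd.DataFrame, config: AnalysisConfig, base: Path, out: Path
) -> tuple[dict[tuple[str, str], conn.ConnectivityMatrix], dict]:
    """Preprocess every subject-condition and return z-scale connectivity."""
    matrices: dict[tuple[str, str], conn.ConnectivityMatrix] = {}
    quality_rows = []
    censored_total = 0
    for _, row in manifest.iterrows():
        ts = prep.ROITimeSeries.from_tsv(base / row["ts_path"], config.tr_seconds)
        motion = prep.MotionParams.from_tsv(base / row["motion_path"])
        cleaned = prep.clean(
            ts,
            motion=motion if config.use_motion_regressors else None,
            low_hz=config.band_low_hz,
            high_hz=config.band_high_hz,
        )
        quality = prep.frame_quality(cleaned, motion)
        if config.scrub:
            threshold = prep.default_dvars_threshold(quality.dvars)
            cleaned, quality = prep.scrub(cleaned, quality, threshold)
        n_censored = int(quality.censored.sum())
        censored_total += n_censored
        if n_censored > 0.2 * ts.n_volumes:
            log.warning(
                "subject %s/%s: %d of %d frames censored",
                row["subject_id"], row["condition"], n_censored, ts.n_volumes,
            )
        cm = conn.to_fisher_z(conn.correlation_matrix(cleaned))
        matrices[(row["subject_id"], row["condition"])] = cm
        quality_rows.append(
            {"subject_id": row["subject_id"], "condition": row["condition"],
             **quality.summary()}
        )
        if config.save_matrices:
            mdir = out / "matrices"
            mdir.mkdir(exist_ok=True)
            cm.to_csv(mdir / f"{row['subject_id']}_{row['condition']}_z.csv")
    (out / "quality.json").write_text(json.dumps(quality_rows, indent=2))
    summary = {
        "n_series": len(matrices),
        "n_frames_censored": censored_total,
        "scrubbed": config.scrub,
    }
    return matrices, summary


def _split_groups(
    manifest: pd.DataFrame,
    matrices: dict[tuple[str, str], conn.ConnectivityMatrix],
    config: AnalysisConfig,
) -> tuple[list[conn.ConnectivityMatrix], list[conn.ConnectivityMatrix], str, str]:
    """Group the connectivity matrices according to the contrast.

    acute_paired: condition 1 vs condition 2, subject-aligned, all groups.
    chronic_unpaired: first-listed condition, group 1 vs group 2.
    """
    conditions = sorted(manifest["condition"].unique())
    if config.contrast == "acute_paired":
        _check_paired(manifest)
        if len(conditions) != 2:
            raise ManifestError(
                f"paired contrast needs exactly 2 conditions, found {conditions}"
            )
        c1, c2 = conditions  # e.g. "post" < "pre" alphabetically; order is echoed
        subjects = sorted(manifest["subject_id"].unique())
        g1 = [matrices[(s, c1)] for s in subjects]
        g2 = [matrices[(s, c2)] for s in subjects]
        return g1, g2, f"condition:{c1}", f"condition:{c2}"
    groups = sorted(manifest["group"].unique())
    if len(groups) != 2:
        raise ManifestError(f"unpaired contrast needs exactly 2 groups, found {groups}")
    cond = conditions[0]
    sub = manifest[manifest["condition"] == cond]
    g1_ids = sorted(sub[sub["group"] == groups[0]]["subject_id"])
    g2_ids = sorted(sub[sub["group"] == groups[1]]["subject_id"])
    g1 = [matrices[(s, cond)] for s in g1_ids]
    g2 = [matrices[(s, cond)] for s in g2_ids]
    return g1, g2, f"group:{groups[0]}", f"group:{groups[1]}"


def _component_record(c: nbsmod.NBSComponent, labels: list[str]) -> dict:
    return {
        "size": c.size,
        "n_nodes": len(c.nodes),
        "p_fwe": round(float(c.p_fwe), 4),
        "edges": [[labels[i], labels[j]] for i, j in c.edges],
    }


def run_contrast(config: AnalysisConfig) -> RunReport:
    """Execute one contrast end to end and write all artifacts."""
    from . import __version__

    base = Path(config.data_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        schema_version=SCHEMA_VERSION,
        config=config.to_dict(),
        config_hash=config.hash(),
        software_version=__version__,
    )
    manifest = read_manifest(base / "manifest.tsv")
    report.stages["manifest"] = {
        "n_rows": len(manifest),
        "n_subjects": int(manifest["subject_id"].nunique()),
        "groups": sorted(manifest["group"].unique().tolist()),
        "conditions": sorted(manifest["condition"].unique().tolist()),
    }
    log.info("manifest: %d rows", len(manifest))

    matrices, prep_summary = _load_and_clean(manifest, config, base, out)
    report.stages["preprocess"] = prep_summary
    log.info("preprocess: %d series cleaned", prep_summary["n_series"])

    g1, g2, name1, name2 = _split_groups(manifest, matrices, config)
    labels = g1[0].roi_labels

    # Difference network + degree.
    t_matrix, df = conn.edgewise_stats(g1, g2, design=config.design)
    net = conn.difference_network(
        t_matrix, df, config.diff_p_threshold, labels, config.design
    )
    net.degree_table().to_csv(out / "degree.tsv", sep="\t", index=False)
    top10 = conn.top_degree_nodes(net, 10)
    edge_rows = []
    from scipy import stats as sps

    for i, j in net.edge_list():
        p = 2.0 * sps.t.sf(abs(t_matrix[i, j]), df)
        edge_rows.append(
            f"{labels[i]}\t{labels[j]}\t{t_matrix[i, j]:.4f}\t{p:.4f}"
        )
    (out / "difference_edges.tsv").write_text(
        "\n".join(["roi_i\troi_j\tt\tp", *edge_rows]) + "\n"
    )
    report.stages["difference_network"] = {
        "comparison": [name1, name2],
        "df": df,
        "p_threshold": config.diff_p_threshold,
        "n_edges": net.n_edges,
        "top_degree": [[n, d] for n, d in top10],
    }
    log.info("difference network: %d edges", net.n_edges)

    # NBS, one directional run per requested sign.
    nbs_out: dict[str, dict] = {}
    for k, sign in enumerate(config.nbs_signs):
        nbs_config = nbsmod.NBSConfig(
            primary_threshold_p=config.nbs_threshold_p,
            n_permutations=config.nbs_permutations,
            alpha=config.nbs_alpha,
            design=config.design,
            sign=sign,
            seed=config.seed + k,
        )
        result = nbsmod.run_nbs(g1, g2, nbs_config)
        sizes, counts = np.unique(result.null_max_sizes, return_counts=True)
        nbs_out[sign] = {
            "threshold_t": round(result.threshold_t, 4),
            "n_permutations": len(result.null_max_sizes),
            "components": [
                _component_record(c, labels) for c in result.components[:20]
            ],
            "n_significant": len(result.significant()),
            "null_max_size_histogram": {
                int(s): int(c) for s, c in zip(sizes, counts)
            },
        }
        for idx, c in enumerate(result.significant()):
            rows = [
                f"{labels[i]}\t{labels[j]}\t{t_matrix[i, j]:.4f}" for i, j in c.edges
            ]
            (out / f"nbs_{sign}_component{idx + 1}.tsv").write_text(
                "\n".join(["roi_i\troi_j\tt", *rows]) + "\n"
            )
        log.info(
            "nbs[%s]: %d components, %d significant",
            sign, len(result.components), len(result.significant()),
        )
    (out / "nbs_result.json").write_text(json.dumps(nbs_out, indent=2))
    report.stages["nbs"] = nbs_out

    # Classification between the two groups/conditions.
    features = clf.features_from_matrices(g1, g2)
    cls = clf.loocv_svm(
        features,
        kernels=config.classify_kernels,
        C_grid=config.classify_C_grid,
        p_threshold=config.classify_p_threshold,
        seed=config.seed,
    )
    perm_p = None
    if config.classify_permutations > 0:
        perm_p = clf.permutation_test_accuracy(
            features,
            cls.accuracy,
            n_perm=config.classify_permutations,
            seed=config.seed,
            kernels=config.classify_kernels,
            C_grid=config.classify_C_grid,
            p_threshold=config.classify_p_threshold,
        )
    report.stages["classification"] = {
        "accuracy": round(cls.accuracy, 4),
        "sensitivity": round(cls.sensitivity, 4),
        "specificity": round(cls.specificity, 4),
        "auc": round(cls.auc, 4),
        "best_kernel": cls.best_kernel,
        "best_C": cls.best_C,
        "permutation_p": round(perm_p, 4) if perm_p is not None else None,
        "grid": {f"{k}:C={c}": round(a, 4) for (k, c), a in cls.grid.items()},
    }
    log.info("classification: accuracy %.3f (%s, C=%g)",
             cls.accuracy, cls.best_kernel, cls.best_C)

    write_report(report, out)
    return report


def write_report(report: RunReport, out_dir: str | Path) -> None:
    """Write report.json and a human-readable report.md."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))

    lines = [
        "# Connectivity contrast report",
        "",
        f"- schema: {report.schema_version}",
        f"- software: connectonet {report.software_version}",
        f"- config hash: `{report.config_hash}`",
        f"- contrast: {report.config.get('contrast')}",
        "",
    ]
    if "difference_network" in report.stages:
        dn = report.stages["difference_network"]
        lines += [
            "## Difference network",
            "",
            f"{dn['n_edges']} edges at p < {dn['p_threshold']} "
            f"({dn['comparison'][0]} vs {dn['comparison'][1]}, df = {dn['df']:g}).",
            "",
            "Top-10 degree regions:",
            "",
            "| region | degree |",
            "| --- | --- |",
        ]
        lines += [f"| {n} | {d} |" for n, d in dn["top_degree"]]
        lines.append("")
    if "nbs" in report.stages:
        lines.append("## Network-based statistic")
        lines.append("")
        for sign, block in report.stages["nbs"].items():
            lines.append(
                f"- sign={sign}: {len(block['components'])} component(s), "
                f"{block['n_significant']} significant at FWE "
                f"(primary t = {block['threshold_t']}, "
                f"M = {block['n_permutations']})"
            )
            for comp in block["components"][:3]:
                lines.append(
                    f"  - size {comp['size']} links / {comp['n_nodes']} nodes, "
                    f"p_fwe = {comp['p_fwe']:.4f}"
                )
        lines.append("")
    if "classification" in report.stages:
        c = report.stages["classification"]
        lines += [
            "## Classification",
            "",
            f"LOOCV accuracy {c['accuracy']:.4f} "
            f"(sensitivity {c['sensitivity']:.4f}, specificity {c['specificity']:.4f}, "
            f"AUC {c['auc']:.4f}) with {c['best_kernel']} kernel, C = {c['best_C']:g}."
            + (
                f" Permutation p = {c['permutation_p']:.4f}."
                if c.get("permutation_p") is not None
                else ""
            ),
            "",
        ]
    (out / "report.md").write_text("\n".join(lines))
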