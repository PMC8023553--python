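"""End-to-end featurization over one or many dimers.

One manifest row = one dimer: a PDB path, the two chain IDs, optionally a
fold class, per-chain PSSMs and a TM-range annotation.  Each dimer yields a
per-residue feature table (class, ASA descriptors, conservation, B-factor,
interaction counts) and a long-format interactions table; dataset-level
outputs are the propensity table, propensity-corrected features, summary
statistics and class-comparison tests, plus a machine-readable run report.
Failures are isolated per row — a bad structure is logged and skipped, and
the batch exit status distinguishes full success (0), fatal (1) and partial
success (2).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import conservation as cons
from . import interactions as ia
from . import stats as st
from . import structure as sio
from . import surface as surf

logger = logging.getLogger("dimerfeat")

EXIT_OK, EXIT_FATAL, EXIT_PARTIAL = 0, 1, 2

#: Feature columns eligible for propensity correction.  relASA is exempt.
CORRECTABLE_FEATURES = [
    "mon_asa", "comp_asa", "delta_asa", "jsd", "b_factor",
    "close_25", "close_40", "hydrophobic", "hbond", "salt_bridge",
    "pi_pi", "t_stack", "cation_pi",
]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    rsa_cutoff: float = 0.20
    interface_cutoff: float = 5.0
    contact_cutoff: float = 5.0
    probe_radius: float = 1.4
    asa_points: int = 960
    background: str | None = None      # explicit background name, or None for fold-based
    fold_class: str | None = None      # alpha_helical | beta_barrel (fallback for manifest rows)
    rel_asa_convention: str = "literal"
    rel_asa_percent: bool = False
    correction: bool = True
    seed: int = 0
    output_dir: str = "dimerfeat_out"
    thresholds: ia.InteractionThresholds = field(default_factory=ia.InteractionThresholds)

    def effective(self) -> dict:
        d = dataclasses.asdict(self)
        return d


_POSITIVE_KEYS = ("rsa_cutoff", "interface_cutoff", "contact_cutoff", "probe_radius")


def validate_config(config: dict | str | Path | None) -> RunConfig:
    """Normalize a config mapping (or YAML path) into a :class:`RunConfig`.

    Unknown keys warn and are ignored; every violated constraint is listed
    in a single error.
    """
    if config is None:
        config = {}
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text()) or {}
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")

    known = {f.name for f in dataclasses.fields(RunConfig)}
    clean = {}
    for key, val in config.items():
        if key not in known:
            warnings.warn(f"unknown config key {key!r} ignored")
            continue
        clean[key] = val
    th = clean.pop("thresholds", None)
    cfg = RunConfig(**clean)
    if th is not None:
        if isinstance(th, ia.InteractionThresholds):
            cfg.thresholds = th
        else:
            valid = {f.name for f in dataclasses.fields(ia.InteractionThresholds)}
            unknown = set(th) - valid
            for k in unknown:
                warnings.warn(f"unknown threshold key {k!r} ignored")
            cfg.thresholds = ia.InteractionThresholds(
                **{k: v for k, v in th.items() if k in valid})

    problems = []
    for key in _POSITIVE_KEYS:
        if getattr(cfg, key) <= 0:
            problems.append(f"{key} must be > 0, got {getattr(cfg, key)}")
    if cfg.asa_points < 10:
        problems.append(f"asa_points must be >= 10, got {cfg.asa_points}")
    if cfg.rel_asa_convention not in ("literal", "buried_fraction"):
        problems.append(f"unknown rel_asa_convention {cfg.rel_asa_convention!r}")
    if cfg.background is not None and cfg.background not in ("blosum62", "slim", "bbtm_tm"):
        problems.append(f"unknown background {cfg.background!r}")
    try:
        cfg.thresholds.validate()
    except ValueError as exc:
        problems.append(str(exc))
    if problems:
        raise ConfigError("invalid configuration: " + "; ".join(problems))
    return cfg


def _pick_background(cfg: RunConfig, fold: str | None) -> cons.BackgroundDistribution | None:
    if cfg.background is not None:
        return cons.get_background(cfg.background)
    fold = fold or cfg.fold_class
    if fold:
        return cons.appropriate_background(fold)
    return None


def featurize_dimer(
    dimer: sio.DimerStructure,
    cfg: RunConfig,
    pssm_a: cons.PSSM | None = None,
    pssm_b: cons.PSSM | None = None,
    background: cons.BackgroundDistribution | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-residue feature table and long-format interaction table."""
    features = surf.classify(
        dimer, cfg.rsa_cutoff, cfg.interface_cutoff, cfg.probe_radius,
        cfg.asa_points, cfg.rel_asa_convention, cfg.rel_asa_percent)

    counts = ia.fingerprint(dimer, cfg.thresholds)
    features = features.merge(counts, on=["pdb_id", "chain", "resi", "icode", "resn"],
                              how="left")

    b_by_key = {r.key: r.mean_b_factor() for r in dimer.residues()}
    features["b_factor"] = [
        b_by_key[(c, i, ic)] for c, i, ic in
        zip(features["chain"], features["resi"], features["icode"])]

    features["jsd"] = np.nan
    if background is not None:
        for chain, pssm in ((dimer.chain_a, pssm_a), (dimer.chain_b, pssm_b)):
            if pssm is None:
                continue
            if pssm.length != len(chain):
                warnings.warn(
                    f"PSSM length {pssm.length} != chain {chain[0].chain_id} length "
                    f"{len(chain)}; conservation skipped for this chain")
                continue
            scores = cons.conservation_profile(pssm, background)
            cid = chain[0].chain_id
            for res, score in zip(chain, scores):
                sel = ((features["chain"] == cid) & (features["resi"] == res.residue_seq)
                       & (features["icode"] == res.insertion_code))
                features.loc[sel, "jsd"] = score

    records = ia.detect_all(dimer, cfg.thresholds)
    return features, ia.records_to_frame(records, dimer.source_id)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a manifest CSV/TSV; missing optional columns become empty."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    if "pdb_path" not in df or "chain_a" not in df or "chain_b" not in df:
        raise ConfigError(f"{path}: manifest needs pdb_path, chain_a, chain_b columns")
    for col in ("fold_class", "pssm_path_a", "pssm_path_b", "tm_annotation_path"):
        if col not in df:
            df[col] = ""
    return df


def _load_dimer(row: pd.Series, cfg: RunConfig) -> sio.DimerStructure:
    chains = sio.sanitize(sio.read_structure(row["pdb_path"]))
    by_id = {ch[0].chain_id: ch for ch in chains}
    for cid in (row["chain_a"], row["chain_b"]):
        if cid not in by_id:
            raise sio.StructureError(f"chain {cid!r} absent from {row['pdb_path']}")
    dimer = sio.DimerStructure(by_id[row["chain_a"]], by_id[row["chain_b"]],
                               source_id=Path(row["pdb_path"]).stem)
    if row.get("tm_annotation_path"):
        annotation = sio.read_tm_annotation(row["tm_annotation_path"])
        dimer = sio.apply_tm_mask(dimer, annotation)
    return dimer


def run(manifest: pd.DataFrame | str | Path, config: dict | RunConfig | None = None) -> dict:
    """Featurize every manifest row; write CSVs and a run report.

    Returns the report dict; ``report['exit_status']`` is 0 when every row
    succeeded, 2 when some rows were skipped and 1 when nothing succeeded.
    Outputs are fully determined by inputs + config.
    """
    cfg = config if isinstance(config, RunConfig) else validate_config(config)
    if not isinstance(manifest, pd.DataFrame):
        manifest = read_manifest(manifest)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    all_features: list[pd.DataFrame] = []
    skipped: list[dict] = []
    processed: list[str] = []
    for idx, row in manifest.iterrows():
        tag = f"{Path(str(row['pdb_path'])).stem}_{row['chain_a']}{row['chain_b']}"
        try:
            if not Path(str(row["pdb_path"])).exists():
                raise sio.StructureError(f"missing file {row['pdb_path']}")
            dimer = _load_dimer(row, cfg)
            background = _pick_background(cfg, row.get("fold_class") or None)
            pssm_a = cons.read_pssm(row["pssm_path_a"], background) if row.get("pssm_path_a") else None
            pssm_b = cons.read_pssm(row["pssm_path_b"], background) if row.get("pssm_path_b") else None
            feats, inter = featurize_dimer(dimer, cfg, pssm_a, pssm_b, background)
        except (sio.StructureError, cons.ConservationError, surf.SurfaceError,
                OSError, ValueError) as exc:
            reason = f"{type(exc).__name__}: {exc}"
            logger.error("SKIP row %s (%s): %s", idx, tag, reason)
            skipped.append({"row": int(idx), "dimer": tag, "reason": reason})
            continue
        feats.to_csv(outdir / f"{tag}_features.csv", index=False)
        inter.to_csv(outdir / f"{tag}_interactions.csv", index=False)
        all_features.append(feats)
        processed.append(tag)

    report: dict = {
        "config": _jsonable(cfg.effective()),
        "n_rows": int(len(manifest)),
        "n_processed": len(processed),
        "processed": processed,
        "skipped": skipped,
    }

    if all_features:
        dataset = pd.concat(all_features, ignore_index=True)
        prop = st.propensities(dataset["class"], dataset["resn"])
        prop.to_csv(outdir / "propensities.csv", index=False)
        feature_cols = [c for c in CORRECTABLE_FEATURES if c in dataset]
        table = dataset
        if cfg.correction:
            table = st.correct_features(dataset, prop, feature_cols)
        summary_cols = [c for c in feature_cols + ["rel_asa"]
                        if table[c].notna().any()]
        summary = st.summarize(table, ["class", "resn"], summary_cols)
        summary.to_csv(outdir / "summary_stats.csv", index=False)
        testable = [c for c in summary_cols if table[c].notna().sum() > 0]
        tests = st.group_tests(table, testable) if table["class"].nunique() > 1 else pd.DataFrame()
        tests.to_csv(outdir / "class_tests.csv", index=False)
        dataset.to_csv(outdir / "dataset_residues.csv", index=False)

        counts = dataset["class"].value_counts().to_dict()
        report["class_counts"] = {k: int(v) for k, v in counts.items()}
        report["n_residues"] = int(len(dataset))

    report["exit_status"] = (
        EXIT_OK if not skipped and processed
        else EXIT_PARTIAL if processed
        else EXIT_FATAL)
    (outdir / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
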