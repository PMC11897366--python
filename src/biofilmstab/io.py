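"""Readers, writers and validation for the pipeline's text formats.

Canonical formats: long (tidy) TSV with a header row for abundance, trait
and biomass tables; Newick for the phylogeny; YAML for design/config; a
JSON manifest with SHA-256 checksums for fixture bundles.  Floats are
written in the shortest decimal form that round-trips exactly and parsed
back with round-trip precision, so read(write(x)) is the identity.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from .config import RegimeDesign, SyntheticWorldConfig
from .errors import ValidationError

log = logging.getLogger(__name__)

ABUNDANCE_COLS = ["plot_id", "treatment", "date", "mag_id", "tpm"]
TRAIT_COLS = ["mag_id", "stress_module_count", "genome_size", "completeness", "mdt"]
BIOMASS_COLS = ["plot_id", "subplot_id", "treatment", "date", "phase", "biomass"]


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{what}: missing columns {missing}")


def validate_abundance(df: pd.DataFrame, tpm_total: float = 1e6, rtol: float = 1e-6) -> pd.DataFrame:
    _require_columns(df, ABUNDANCE_COLS, "abundance table")
    if df[["plot_id", "date", "mag_id"]].duplicated().any():
        dup = df[df[["plot_id", "date", "mag_id"]].duplicated()].iloc[0]
        raise ValidationError(
            f"duplicate abundance key (plot {dup['plot_id']}, date {dup['date']}, {dup['mag_id']})"
        )
    neg = df.index[df["tpm"] < 0]
    if len(neg):
        raise ValidationError(f"negative TPM at row {int(neg[0])}")
    sums = df.groupby(["plot_id", "date"])["tpm"].sum()
    bad = sums[np.abs(sums - tpm_total) > rtol * tpm_total]
    if len(bad):
        (plot, date), val = next(iter(bad.items())), None
        raise ValidationError(
            f"TPM for plot {plot[0] if isinstance(plot, tuple) else plot} does not close to {tpm_total:g}"
        )
    return df


def validate_traits(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, TRAIT_COLS, "trait table")
    if df["mag_id"].duplicated().any():
        raise ValidationError(
            f"duplicate MAG row: {df.loc[df['mag_id'].duplicated(), 'mag_id'].iloc[0]}"
        )
    if (df["stress_module_count"] < 0).any():
        raise ValidationError("negative stress-module count")
    if not np.isfinite(df["mdt"]).all() or (df["mdt"] <= 0).any():
        raise ValidationError("MDT must be finite and positive")
    if (df["completeness"] > 100).any() or (df["completeness"] <= 0).any():
        raise ValidationError("completeness must lie in (0, 100]")
    return df


def validate_biomass(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, BIOMASS_COLS, "biomass table")
    if (df["biomass"] <= 0).any():
        row = df.index[df["biomass"] <= 0][0]
        raise ValidationError(f"non-positive biomass at row {int(row)}")
    if not set(df["phase"]) <= {"pre", "post"}:
        raise ValidationError("phase must be 'pre' or 'post'")
    for plot, sub in df.groupby("plot_id"):
        dates = sub.sort_values("date")
        if (
            dates.groupby("date")["phase"].nunique().max() > 1
            or not dates.drop_duplicates("date")["date"].is_monotonic_increasing
        ):
            raise ValidationError(f"inconsistent dates/phases for plot {plot}")
    return df


def check_tree_covers(tree: dendropy.Tree, mags) -> None:
    from .config import UNBINNED_ID

    tips = {t.label for t in tree.taxon_namespace}
    missing = sorted(set(mags) - tips - {UNBINNED_ID})
    if missing:
        raise ValidationError(f"tree missing MAGs: {', '.join(missing)}")


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{what}: file not found: {path}")
    try:
        return pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise ValidationError(f"{what}: cannot parse {path}: {exc}") from exc


def read_abundance(path) -> pd.DataFrame:
    return validate_abundance(_read_tsv(path, "abundance table"))


def read_traits(path) -> pd.DataFrame:
    return validate_traits(_read_tsv(path, "trait table"))


def read_biomass(path) -> pd.DataFrame:
    return validate_biomass(_read_tsv(path, "biomass table"))


def read_tree(path) -> dendropy.Tree:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"tree file not found: {path}")
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    n_zero = sum(
        1
        for e in tree.preorder_edge_iter()
        if e.head_node.parent_node is not None and (e.length is None or e.length == 0)
    )
    if n_zero:
        log.warning("tree has %d zero/absent branch lengths", n_zero)
    return tree


def write_tsv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def write_tree(tree: dendropy.Tree, path) -> Path:
    path = Path(path)
    tree.write(
        path=str(path), schema="newick", suppress_rooting=True, unquoted_underscores=True
    )
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_bundle(world: dict, directory) -> dict:
    """Write a complete synthetic bundle plus a checksummed manifest.

    ``world`` is the dict returned by :func:`biofilmstab.synthesis.generate_world`.
    Emits abundance.tsv, traits.tsv, tree.nwk, biomass.tsv, design.yaml and
    manifest.json; the tables round-trip bit-identically through the readers.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {
        "abundance.tsv": write_tsv(world["abundances"], directory / "abundance.tsv"),
        "traits.tsv": write_tsv(world["traits"], directory / "traits.tsv"),
        "biomass.tsv": write_tsv(world["biomass"], directory / "biomass.tsv"),
        "tree.nwk": write_tree(world["tree"], directory / "tree.nwk"),
    }
    design_doc = {
        "design": dataclasses.asdict(world["design"]),
        "world": dataclasses.asdict(world["world"]),
        "regime": {
            "pulses": {k: list(map(float, v)) for k, v in world["regime"]["pulses"].items()},
            "pulse_days": world["regime"]["pulse_days"],
            "extremes": world["regime"]["extremes"],
        },
    }
    design_path = directory / "design.yaml"
    design_path.write_text(yaml.safe_dump(design_doc, sort_keys=True))
    files["design.yaml"] = design_path
    manifest = {
        "seed": world["seed"],
        "config_hash": world["world"].config_hash(),
        "files": {name: _sha256(p) for name, p in files.items()},
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def read_fixture_bundle(directory, verify: bool = True) -> dict:
    """Load a bundle written by :func:`write_fixture_bundle`, checking integrity."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    if verify:
        for name, digest in manifest["files"].items():
            actual = _sha256(directory / name)
            if actual != digest:
                raise ValidationError(f"manifest checksum mismatch for {name}")
    design_doc = yaml.safe_load((directory / "design.yaml").read_text())
    d = design_doc["design"]
    for key in ("treatments", "pulse_days", "sampling_dates_biomass", "sampling_dates_community"):
        d[key] = tuple(d[key])
    design = RegimeDesign(**d)
    w = design_doc["world"]
    from .config import BiomassEffects, TreatmentEffects

    for key in ("baseline_lognormal_mu_sigma", "binned_fraction_beta"):
        w[key] = tuple(w[key])
    w["treatment_effects"] = {
        k: TreatmentEffects(**v) for k, v in w["treatment_effects"].items()
    }
    w["biomass_effects"] = {k: BiomassEffects(**v) for k, v in w["biomass_effects"].items()}
    world_cfg = SyntheticWorldConfig(**w)
    if verify and manifest["seed"] != world_cfg.seed:
        raise ValidationError("manifest seed does not match the stored configuration")
    abundances = read_abundance(directory / "abundance.tsv")
    traits = read_traits(directory / "traits.tsv")
    tree = read_tree(directory / "tree.nwk")
    check_tree_covers(tree, abundances["mag_id"].unique())
    return {
        "design": design,
        "world": world_cfg,
        "seed": manifest["seed"],
        "regime": design_doc["regime"],
        "abundances": abundances,
        "traits": traits,
        "tree": tree,
        "biomass": read_biomass(directory / "biomass.tsv"),
    }
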