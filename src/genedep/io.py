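"""Readers and writers for the plain-text interchange formats.

Matrices travel as TSV (genes in the first column, samples across),
screen plates as CSV, knockdown and scorecard tables as TSV, and scoring
specifications as YAML::

    blocks:
      A_gex: {cap: 6}
      ...
    features:
      - name: tnbc_normal_log2fc
        block: A_gex
        threshold1: 1.0
        threshold2: 2.0
        weight: 2.0
        direction: larger
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .profile import GeneCentricProfile
from .scoring import BlockSpec, FeatureSpec

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_profile",
    "write_profile",
    "read_plates",
    "write_plates",
    "load_specs",
    "save_specs",
]


def read_matrix(path) -> pd.DataFrame:
    """Gene-by-sample TSV with gene identifiers in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def write_profile(profile: GeneCentricProfile, directory) -> None:
    """Write ``cn.tsv``, ``gex.tsv`` and ``samples.tsv`` into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_matrix(profile.cn, directory / "cn.tsv")
    write_matrix(profile.gex, directory / "gex.tsv")
    profile.samples.to_csv(directory / "samples.tsv", sep="\t")


def read_profile(directory) -> GeneCentricProfile:
    directory = Path(directory)
    return GeneCentricProfile(
        cn=read_matrix(directory / "cn.tsv"),
        gex=read_matrix(directory / "gex.tsv"),
        samples=pd.read_csv(directory / "samples.tsv", sep="\t", index_col=0),
    )


def write_plates(plates: pd.DataFrame, path) -> None:
    plates.to_csv(path, index=False)


def read_plates(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    for col in ("gene", "oligo", "cell_line"):
        if col in df.columns:
            df[col] = df[col].fillna("")
    return df


def load_specs(path) -> tuple[list[FeatureSpec], list[BlockSpec]]:
    """Load feature and block scoring specifications from YAML."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    blocks = [
        BlockSpec(block=name, cap=float(spec["cap"]))
        for name, spec in doc.get("blocks", {}).items()
    ]
    features = [
        FeatureSpec(
            name=f["name"],
            block=f["block"],
            threshold1=float(f["threshold1"]),
            threshold2=float(f["threshold2"]),
            weight=float(f.get("weight", 1.0)),
            direction=f.get("direction", "larger"),
        )
        for f in doc.get("features", [])
    ]
    return features, blocks


def save_specs(features, blocks, path) -> None:
    doc = {
        "blocks": {b.block: {"cap": b.cap} for b in blocks},
        "features": [
            {
                "name": f.name,
                "block": f.block,
                "threshold1": f.threshold1,
                "threshold2": f.threshold2,
                "weight": f.weight,
                "direction": f.direction,
            }
            for f in features
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
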