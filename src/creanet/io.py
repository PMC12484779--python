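"""Readers and writers for the pipeline's plain-text interchange formats.

* lexicons in word2vec text format (header ``vocab_count dim``, then one
  ``token v1 ... vd`` line per word);
* stories as TSV with columns ``id``, ``condition``, ``text``;
* region time series as one delimited T x N matrix file per
  subject/condition/trial plus a manifest TSV and an atlas-label TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .edges import RegionTimeSeries
from .text import EmbeddingLexicon, TokenSequence

__all__ = [
    "write_lexicon",
    "read_lexicon",
    "write_stories",
    "read_stories",
    "write_bold_set",
    "read_bold_set",
    "write_atlas",
    "read_atlas",
]


# ---------------------------------------------------------------------------
# word2vec text format


def write_lexicon(lexicon: EmbeddingLexicon, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"{len(lexicon)} {lexicon.dim}\n")
        for tok in sorted(lexicon.vectors):
            vec = " ".join(repr(float(v)) for v in lexicon.vectors[tok])
            fh.write(f"{tok} {vec}\n")


def read_lexicon(path: str | Path) -> EmbeddingLexicon:
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed word2vec header")
        n, dim = int(header[0]), int(header[1])
        vectors: dict[str, np.ndarray] = {}
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(f"{path}: line with {len(parts) - 1} values, expected {dim}")
            vectors[parts[0]] = np.array(parts[1:], dtype=float)
    if len(vectors) != n:
        raise ValueError(f"{path}: header promised {n} words, found {len(vectors)}")
    return EmbeddingLexicon(vectors=vectors, dim=dim)


# ---------------------------------------------------------------------------
# stories


def write_stories(stories: list[TokenSequence], path: str | Path) -> None:
    rows = [
        {"id": s.source_id, "condition": s.condition if s.condition is not None else "", "text": " ".join(s.tokens)}
        for s in stories
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_stories(path: str | Path) -> list[TokenSequence]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for _, row in df.iterrows():
        out.append(
            TokenSequence(
                tokens=str(row["text"]).split(),
                source_id=str(row["id"]),
                condition=str(row["condition"]) or None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# atlas and BOLD matrices


def write_atlas(atlas: list[str], path: str | Path) -> None:
    pd.DataFrame({"node_index": range(len(atlas)), "network_name": atlas}).to_csv(
        path, sep="\t", index=False
    )


def read_atlas(path: str | Path) -> list[str]:
    df = pd.read_csv(path, sep="\t")
    return df.sort_values("node_index")["network_name"].astype(str).tolist()


def write_bold_set(series: list[RegionTimeSeries], out_dir: str | Path) -> Path:
    """One T x N matrix file per (subject, condition, trial) + manifest.

    Matrices are stored time-major (T rows, N columns) as tab-delimited
    text; the manifest TSV records file, subject, condition, trial.
    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    atlas = None
    for ts in series:
        if atlas is None:
            atlas = ts.atlas
        elif ts.atlas != atlas:
            raise ValueError("all series must share one atlas")
        fname = f"{ts.subject}_{ts.condition}_trial{ts.trial:02d}.tsv"
        np.savetxt(out_dir / fname, ts.data.T, delimiter="\t")
        rows.append(
            {"file": fname, "subject": ts.subject, "condition": ts.condition, "trial": ts.trial}
        )
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    if atlas is not None:
        write_atlas(atlas, out_dir / "atlas.tsv")
    return manifest


def read_bold_set(manifest_path: str | Path) -> list[RegionTimeSeries]:
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path, sep="\t")
    atlas_file = base / "atlas.tsv"
    atlas = read_atlas(atlas_file) if atlas_file.exists() else None
    out = []
    for _, row in df.iterrows():
        mat = np.loadtxt(base / row["file"], delimiter="\t")
        out.append(
            RegionTimeSeries(
                data=mat.T,
                atlas=list(atlas) if atlas is not None else None,
                subject=str(row["subject"]),
                condition=str(row["condition"]),
                trial=int(row["trial"]),
                z_scored=False,
            )
        )
    return out
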