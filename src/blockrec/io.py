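"""Readers and writers for the MovieLens-100k file dialects and run artifacts.

Ratings come as tab-separated ``user \\t item \\t rating \\t timestamp``
lines (``u.data`` and the ``u1.base``/``u1.test`` ... split files); user
metadata as ``id|age|gender|occupation|zip`` and item metadata as
pipe-separated records ending in binary genre flags (``u.user`` /
``u.item``).  Partition samples persist as a plain-text, versioned format
with run-length-encoded assignments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import RatingDataset, build_dataset
from .inference import PartitionSample, SamplerConfig
from .synthetic import GeneratorConfig

__all__ = [
    "MOVIELENS_GENRES",
    "read_ratings",
    "write_ratings",
    "read_user_metadata",
    "read_item_metadata",
    "save_sample",
    "load_sample",
    "RunConfig",
]

# canonical MovieLens-100k genre flag order
MOVIELENS_GENRES = [
    "unknown", "Action", "Adventure", "Animation", "Children's", "Comedy",
    "Crime", "Documentary", "Drama", "Fantasy", "Film-Noir", "Horror",
    "Musical", "Mystery", "Romance", "Sci-Fi", "Thriller", "War", "Western",
]


def read_ratings(path, dialect: str = "movielens-tab", K: int | None = None) -> RatingDataset:
    """Parse a tab-separated ratings file into a :class:`RatingDataset`.

    The timestamp column is ignored.  ``K`` is inferred as the maximum
    rating unless overridden; a rating above a forced ``K`` is an error.
    """
    if dialect != "movielens-tab":
        raise ValueError(f"unknown dialect {dialect!r}")
    triples = []
    max_r = 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected at least 3 tab-separated fields")
            try:
                u, i, r = int(parts[0]), int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer user/item/rating") from None
            if r < 1:
                raise ValueError(f"{path}:{lineno}: rating {r} below 1")
            triples.append((u, i, r))
            max_r = max(max_r, r)
    k = K if K is not None else max(max_r, 2)
    try:
        return build_dataset(triples, K=k)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_ratings(dataset: RatingDataset, path) -> None:
    """Write the MovieLens tab dialect; timestamps are zero-filled."""
    with open(path, "w") as fh:
        for uid, iid, r in dataset.triples():
            fh.write(f"{uid}\t{iid}\t{r}\t0\n")


def read_user_metadata(path) -> pd.DataFrame:
    """Parse ``id|age|gender|occupation|zip`` records, indexed by user id."""
    rows = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("|")
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 pipe-separated fields")
            try:
                uid, age = int(parts[0]), int(parts[1])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer id or age") from None
            if uid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate user id {uid}")
            seen.add(uid)
            rows.append(
                {"id": uid, "age": age, "gender": parts[2], "occupation": parts[3], "zip": parts[4]}
            )
    return pd.DataFrame(rows, columns=["id", "age", "gender", "occupation", "zip"]).set_index("id")


def read_item_metadata(path, genre_names: list[str] | None = None) -> pd.DataFrame:
    """Parse pipe-separated item records with trailing binary genre flags.

    Returns ``id``, ``title``, ``genres`` (a set of genre names) and
    ``no_genre`` flagging items whose flags are all zero — those are
    excluded from genre-overlap analysis because the Jaccard index is
    undefined for empty sets.
    """
    genre_names = genre_names or MOVIELENS_GENRES
    n_flags = len(genre_names)
    rows = []
    seen = set()
    with open(path, encoding="latin-1") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("|")
            if len(parts) < 2 + n_flags:
                raise ValueError(
                    f"{path}:{lineno}: expected id, title and {n_flags} genre flags"
                )
            try:
                iid = int(parts[0])
                flags = [int(x) for x in parts[-n_flags:]]
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer id or genre flag") from None
            if any(f not in (0, 1) for f in flags):
                raise ValueError(f"{path}:{lineno}: genre flags must be 0/1")
            if iid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate item id {iid}")
            seen.add(iid)
            genres = {g for g, f in zip(genre_names, flags) if f}
            rows.append(
                {"id": iid, "title": parts[1], "genres": genres, "no_genre": not genres}
            )
    return pd.DataFrame(rows, columns=["id", "title", "genres", "no_genre"]).set_index("id")


# ---------------------------------------------------------------------------
# Partition-sample persistence (plain text, versioned)

_SAMPLE_MAGIC = "blockrec-sample 1"


def _rle(values: np.ndarray) -> str:
    out = []
    run_val, run_len = None, 0
    for v in values:
        v = int(v)
        if v == run_val:
            run_len += 1
        else:
            if run_val is not None:
                out.append(f"{run_val}x{run_len}" if run_len > 1 else str(run_val))
            run_val, run_len = v, 1
    if run_val is not None:
        out.append(f"{run_val}x{run_len}" if run_len > 1 else str(run_val))
    return ",".join(out)


def _unrle(text: str) -> np.ndarray:
    out: list[int] = []
    if text:
        for token in text.split(","):
            if "x" in token:
                v, n = token.split("x")
                out.extend([int(v)] * int(n))
            else:
                out.append(int(token))
    return np.asarray(out, dtype=np.int64)


def save_sample(sample: PartitionSample, path) -> None:
    """Persist a partition sample as versioned plain text."""
    with open(path, "w") as fh:
        fh.write(f"{_SAMPLE_MAGIC}\n")
        fh.write(f"n_samples={len(sample)} acceptance_rate={sample.acceptance_rate!r}\n")
        for s in range(len(sample)):
            fh.write(
                f"H={float(sample.h_values[s])!r} chain={int(sample.chain_ids[s])} "
                f"sweep={int(sample.sweep_indices[s])}\n"
            )
            fh.write(_rle(sample.user_samples[s]) + "\n")
            fh.write(_rle(sample.item_samples[s]) + "\n")


def load_sample(path) -> PartitionSample:
    with open(path) as fh:
        magic = fh.readline().strip()
        if magic != _SAMPLE_MAGIC:
            raise ValueError(f"{path}: not a blockrec sample file (header {magic!r})")
        header = dict(kv.split("=") for kv in fh.readline().split())
        n = int(header["n_samples"])
        rate = float(header.get("acceptance_rate", "nan"))
        sigmas, taus, hs, chains, sweeps = [], [], [], [], []
        for _ in range(n):
            meta = dict(kv.split("=") for kv in fh.readline().split())
            hs.append(float(meta["H"]))
            chains.append(int(meta["chain"]))
            sweeps.append(int(meta["sweep"]))
            sigmas.append(_unrle(fh.readline().strip()))
            taus.append(_unrle(fh.readline().strip()))
    return PartitionSample(
        np.asarray(sigmas), np.asarray(taus), np.asarray(hs),
        np.asarray(chains, dtype=np.int64), np.asarray(sweeps, dtype=np.int64), rate,
    )


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Paths, sampler/generator settings and algorithm selection for a run.

    Loadable from a flat JSON file; command-line flags override file values.
    """

    train_path: str | None = None
    test_path: str | None = None
    user_metadata_path: str | None = None
    item_metadata_path: str | None = None
    output_dir: str = "."
    algorithms: list[str] = field(default_factory=lambda: ["sbm", "naive"])
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    log_level: str = "INFO"

    @staticmethod
    def from_file(path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        sampler = SamplerConfig(**raw.pop("sampler", {}))
        generator = GeneratorConfig(**raw.pop("generator", {}))
        return RunConfig(sampler=sampler, generator=generator, **raw)
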