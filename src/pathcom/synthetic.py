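"""Synthetic gene-set collections with planted community structure.

The generator emulates the overlap structure of curated pathway
databases: K disjoint community gene pools plus one shared background
pool. Each pathway draws a ``within_fraction`` share of its genes from
its community's pool and the remainder uniformly from the background,
so pathways of the same community overlap strongly while unrelated
pathways overlap only by chance through the background. Pathway names
carry a community-specific contiguous 3-token core (plus a source tag
and a unique suffix), giving the labelling stage a recoverable ground
truth, and a category map records the planted membership for NMI
evaluation. Generation is fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import yaml

from .community import Partition
from .geneset_io import CategoryMap, GeneSet, GeneSetCollection, infer_source

#: source tags cycled round-robin over pathways; the first four are the
#: recognised database identifiers so tokenisation strips them, as it
#: would for real MSigDB names
_SOURCE_TAGS = ("KEGG", "REACTOME", "GOBP", "GOMF")

#: vocabulary the community name cores are drawn from (biology-flavoured,
#: none of them stop words or database identifiers)
_CORE_VOCABULARY = (
    "signal", "kinase", "membrane", "transport", "cycle", "repair",
    "immune", "lipid", "oxidative", "chromatin", "ribosome", "splicing",
    "adhesion", "apoptosis", "glycolysis", "receptor", "transcription",
    "translation", "folding", "secretion", "synapse", "matrix", "mitotic",
    "nuclear", "vesicle", "calcium", "interferon", "proteolysis",
    "hypoxia", "stress", "autophagy", "ubiquitin", "telomere", "cilium",
    "peroxisome", "lysosome", "golgi", "spindle", "helicase", "methylation",
)


@dataclass
class SyntheticSpec:
    """Parameters of a planted-community gene-set collection.

    Defaults give five clearly separated but non-trivial communities:
    20 pathways of 40 genes each per community, 80% of every pathway
    drawn from its own 200-gene pool and 20% from a 2000-gene shared
    background.
    """

    n_communities: int = 5
    pathways_per_community: int | tuple[int, int] = 20
    pool_size: int = 200
    background_size: int = 2000
    set_size: int | tuple[int, int] = 40
    within_fraction: float = 0.8
    n_sources: int = 4
    seed: int = 7

    def __post_init__(self) -> None:
        if not (0.0 < self.within_fraction <= 1.0):
            raise ValueError("within_fraction must be in (0, 1]")
        for name in ("n_communities", "pool_size", "background_size", "n_sources"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("pathways_per_community", "set_size"):
            v = getattr(self, name)
            if isinstance(v, int):
                if v < 1:
                    raise ValueError(f"{name} must be positive")
            else:
                lo, hi = v
                if lo < 1 or hi < lo:
                    raise ValueError(f"{name} range must satisfy 1 <= lo <= hi")
        max_size = self.set_size if isinstance(self.set_size, int) else self.set_size[1]
        max_within = round(self.within_fraction * max_size)
        if max_within > self.pool_size:
            raise ValueError(
                f"community pool too small: need up to {max_within} within-pool "
                f"genes per pathway but pool_size={self.pool_size}"
            )
        if max_size - round(self.within_fraction * max_size) > self.background_size:
            raise ValueError("background pool too small for requested set sizes")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for key in ("pathways_per_community", "set_size"):
            if isinstance(d[key], tuple):
                d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        d = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("pathways_per_community", "set_size"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


class SyntheticData(NamedTuple):
    collection: GeneSetCollection
    truth: Partition
    categories: CategoryMap
    vocabulary: dict[int, tuple[str, str, str]]


def _draw(rng: np.random.Generator, value: int | tuple[int, int]) -> int:
    if isinstance(value, int):
        return value
    lo, hi = value
    return int(rng.integers(lo, hi + 1))


def generate(spec: SyntheticSpec) -> SyntheticData:
    """Generate a collection, planted truth partition, category map and
    the per-community name-core vocabulary."""
    rng = np.random.default_rng(spec.seed)
    k = spec.n_communities

    pools = [
        [f"C{c:02d}G{i:04d}" for i in range(spec.pool_size)] for c in range(k)
    ]
    background = [f"BGG{i:05d}" for i in range(spec.background_size)]

    # community name cores: 3 distinct words each, all communities disjoint
    need = 3 * k
    vocab = list(_CORE_VOCABULARY)
    if need > len(vocab):
        vocab += [f"theme{i:03d}" for i in range(need - len(vocab))]
    chosen = rng.choice(len(vocab), size=need, replace=False)
    cores = {
        c: tuple(vocab[j] for j in chosen[3 * c : 3 * c + 3]) for c in range(k)
    }

    sets: list[GeneSet] = []
    assignment: dict[str, int] = {}
    categories: dict[str, str] = {}
    idx = 0
    for c in range(k):
        n_paths = _draw(rng, spec.pathways_per_community)
        for _ in range(n_paths):
            size = _draw(rng, spec.set_size)
            n_within = round(spec.within_fraction * size)
            n_bg = size - n_within
            genes = {str(g) for g in rng.choice(pools[c], size=n_within, replace=False)}
            if n_bg:
                genes |= {str(g) for g in rng.choice(background, size=n_bg, replace=False)}
            tag = (
                _SOURCE_TAGS[idx % spec.n_sources]
                if idx % spec.n_sources < len(_SOURCE_TAGS)
                else f"SRC{idx % spec.n_sources}"
            )
            core = "_".join(w.upper() for w in cores[c])
            name = f"{tag}_{core}_VAR{idx:04d}"
            sets.append(
                GeneSet(id=name, name=name, source=infer_source(name), genes=frozenset(genes))
            )
            assignment[name] = c
            categories[name] = f"community_{c}"
            idx += 1

    collection = GeneSetCollection(sets)
    truth = Partition(dict(assignment), resolution=None, seed=spec.seed)
    return SyntheticData(collection, truth, CategoryMap(categories), cores)


def write_dataset(data: SyntheticData, outdir: str | Path) -> dict[str, Path]:
    """Write GMT + truth partition TSV + category TSV; returns the paths."""
    from .geneset_io import write_category_map, write_gmt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gmt": outdir / "synthetic.gmt",
        "truth": outdir / "truth_partition.tsv",
        "categories": outdir / "categories.tsv",
    }
    write_gmt(data.collection, paths["gmt"])
    data.truth.write_tsv(paths["truth"])
    write_category_map(data.categories, paths["categories"])
    return paths
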