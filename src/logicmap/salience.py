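"""Which features did evolution wire into the circuits?

Because gates connect to input bits only when the connection survives
selection, the wiring of an evolved committee is an unbiased record of
which features helped.  A member *recognizes* a feature as soon as at
least one of that feature's bits appears among its gate inputs (raw
connectivity; reachability of an output is not required, though a pruned
variant is available).  Bit b belongs to feature ``b // bits_per_feature``.

The per-feature recognition counts across a committee rank feature
importance, and thresholding them yields a reduced-feature dataset on
which evolution can be rerun — the full-scale protocol kept features
recognized by at least 6 of 60 networks.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .data import PairDataset
from .genome import CircuitNetwork, used_input_bits


@dataclasses.dataclass
class RecognitionTable:
    """Recognition counts for a committee.

    ``feature_counts[f]`` is the number of members reading any bit of
    feature f; ``member_bit_counts`` / ``member_feature_counts`` give per
    member the number of distinct input bits and distinct features read.
    """

    feature_counts: np.ndarray
    member_bit_counts: np.ndarray
    member_feature_counts: np.ndarray
    bits_per_feature: int

    @property
    def n_features(self) -> int:
        return int(self.feature_counts.size)

    @property
    def n_members(self) -> int:
        return int(self.member_bit_counts.size)


def _reachable_input_bits(network: CircuitNetwork) -> set[int]:
    """Input bits with a gate path to an output node (pruned variant)."""
    base = network.output_base
    live = set(range(base, network.state_size))
    changed = True
    while changed:
        changed = False
        for g in network.gates:
            if any(a in live for a in g.output_addrs):
                for a in g.input_addrs:
                    if a not in live:
                        live.add(a)
                        changed = True
    return {a for a in live if a < network.n_inputs}


def recognition_table(
    members: Sequence[CircuitNetwork],
    bits_per_feature: int,
    n_features: int,
    reachable_only: bool = False,
) -> RecognitionTable:
    """Tally which features each committee member is wired to.

    ``members`` may be a committee object or a plain list of networks.
    ``reachable_only`` switches to the output-reachability-pruned variant
    of the recognition rule.
    """
    members = list(getattr(members, "members", members))
    if not members:
        raise ValueError("recognition table needs a non-empty committee")
    width = bits_per_feature * n_features
    for m in members:
        if m.n_inputs != width:
            raise ValueError(
                f"member input width {m.n_inputs} != "
                f"{bits_per_feature} bits x {n_features} features"
            )
    feature_counts = np.zeros(n_features, dtype=int)
    bit_counts = np.zeros(len(members), dtype=int)
    feat_counts = np.zeros(len(members), dtype=int)
    for k, m in enumerate(members):
        bits = _reachable_input_bits(m) if reachable_only else used_input_bits(m)
        feats = {b // bits_per_feature for b in bits}
        bit_counts[k] = len(bits)
        feat_counts[k] = len(feats)
        for f in feats:
            feature_counts[f] += 1
    return RecognitionTable(feature_counts, bit_counts, feat_counts, bits_per_feature)


def recognition_stats(table: RecognitionTable) -> dict[str, float]:
    """Summary statistics mirroring the committee-level reporting tables.

    Means and medians of networks-per-feature and of bits/features
    recognized per member; the median of an even count is the midpoint.
    """
    return {
        "mean_networks_per_feature": float(np.mean(table.feature_counts)),
        "median_networks_per_feature": float(np.median(table.feature_counts)),
        "mean_bits_per_member": float(np.mean(table.member_bit_counts)),
        "median_bits_per_member": float(np.median(table.member_bit_counts)),
        "mean_features_per_member": float(np.mean(table.member_feature_counts)),
        "median_features_per_member": float(np.median(table.member_feature_counts)),
    }


def top_features(table: RecognitionTable, k: int) -> list[tuple[int, int]]:
    """The k most-recognized features as (feature index, count).

    Sorted by descending count; ties broken by ascending feature index so
    the ranking is deterministic.
    """
    order = sorted(
        range(table.n_features), key=lambda f: (-table.feature_counts[f], f)
    )
    return [(f, int(table.feature_counts[f])) for f in order[:k]]


def reduced_dataset(
    dataset: PairDataset, table: RecognitionTable, min_networks: int
) -> tuple[PairDataset, list[int]]:
    """Keep only features recognized by at least ``min_networks`` members.

    Returns the filtered dataset plus the old->new index map (a list
    whose position n holds the original index of new column n).  Any
    encoder must be refitted on the reduced data before reuse.
    """
    if table.n_features != dataset.n_features:
        raise ValueError("recognition table does not match the dataset")
    keep = [f for f in range(table.n_features)
            if table.feature_counts[f] >= min_networks]
    if not keep:
        raise ValueError("no features survive the recognition threshold")
    metas = None
    if dataset.feature_metas is not None:
        metas = [
            dataclasses.replace(dataset.feature_metas[f], index=n)
            for n, f in enumerate(keep)
        ]
    reduced = PairDataset(
        dataset.labels,
        dataset.protein_ids,
        dataset.res_i,
        dataset.res_j,
        dataset.features[:, keep],
        metas,
    )
    return reduced, keep


def write_recognition_report(table: RecognitionTable, path,
                             group_map: dict[int, str] | None = None) -> None:
    """Tab-separated per-feature counts plus a per-member summary.

    ``group_map`` (feature index -> group label, e.g. from a feature-group
    map file) annotates each feature row when provided.
    """
    stats = recognition_stats(table)
    with open(path, "w") as fh:
        for key, value in stats.items():
            fh.write(f"# {key}={value:.4f}\n")
        fh.write("feature\tnetworks" + ("\tgroup" if group_map else "") + "\n")
        for f in range(table.n_features):
            row = f"{f}\t{int(table.feature_counts[f])}"
            if group_map:
                row += f"\t{group_map.get(f, 'NA')}"
            fh.write(row + "\n")


def read_group_map(path) -> dict[int, str]:
    """Feature-group map file: ``feature_index<TAB>group_label`` per line."""
    mapping: dict[int, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            idx, _, label = line.partition("\t")
            mapping[int(idx)] = label.strip()
    return mapping


def plot_recognition_histogram(table: RecognitionTable, path) -> None:
    """Histogram of how many features are recognized by n members."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    bins = np.arange(table.n_members + 2) - 0.5
    ax.hist(table.feature_counts, bins=bins, color="#4878a8", edgecolor="black")
    ax.set_xlabel("networks recognizing the feature")
    ax.set_ylabel("number of features")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
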