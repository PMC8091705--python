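"""Shared fixtures: tiny matrices, toy flow graphs, and text-format writers."""

from __future__ import annotations

import numpy as np
import pytest

from stableflow.flownet import LDGraph
from stableflow.io_formats import CASE, CONTROL, GenotypeMatrix, VariantKey
from stableflow.selection_stability import FoldSelection


def vk(chrom, pos, ref="A", alt="T"):
    return VariantKey(str(chrom), int(pos), ref, alt)


@pytest.fixture
def tiny_binary_matrix():
    """4 samples x 4 binary variants on two chromosomes."""
    variants = [vk(1, 10), vk(1, 20), vk(2, 10), vk(2, 30)]
    values = np.array(
        [
            [1, 0, 1, 0],
            [1, 1, 0, 0],
            [0, 0, 1, 1],
            [0, 1, 0, 1],
        ],
        dtype=np.int8,
    )
    labels = np.array([CASE, CASE, CONTROL, CONTROL], dtype=object)
    return GenotypeMatrix(values, ["s1", "s2", "s3", "s4"], variants, labels)


def two_chain_graph(k=5):
    """Toy LD graph: one cross-fold chain per chromosome, both spanning folds 1..k.

    Chromosome 1 holds variants 1A..1D and chromosome 2 holds 2A..2D; in each
    fold one variant per chromosome is selected and consecutive selections
    are in LD, so each chromosome contributes exactly one source-to-sink
    chain after source/sink augmentation.
    """
    chain1 = ["1A", "1B", "1B", "1C", "1C"][:k]
    chain2 = ["2A", "2B", "2C", "2C", "2D"][:k]

    def key(name, fold):
        chrom = name[0]
        pos = ord(name[1]) - ord("A") + 1
        return VariantKey(chrom, pos, "A", "T")

    nodes = {f: [key(chain1[f - 1], f), key(chain2[f - 1], f)] for f in range(1, k + 1)}
    edges = []
    for f in range(1, k):
        for chain in (chain1, chain2):
            edges.append(
                (
                    (key(chain[f - 1], f).id, f, "whole"),
                    (key(chain[f], f + 1).id, f + 1, "whole"),
                )
            )
    return LDGraph(k=k, nodes=nodes, edges=edges)


@pytest.fixture
def fig6_graph():
    return two_chain_graph(k=5)


def random_layered_graph(rng, max_variant_nodes=12, k=5):
    """Random k-partite LD graph with at most ``max_variant_nodes`` nodes."""
    n_nodes = rng.integers(2, max_variant_nodes + 1)
    folds = rng.integers(1, k + 1, size=n_nodes)
    chroms = rng.integers(1, 3, size=n_nodes)
    nodes: dict[int, list[VariantKey]] = {f: [] for f in range(1, k + 1)}
    keys = []
    for i, (f, c) in enumerate(zip(folds, chroms)):
        key = VariantKey(str(c), i + 1, "A", "T")
        nodes[int(f)].append(key)
        keys.append((key, int(f), int(c)))
    edges = []
    for a, fa, ca in keys:
        for b, fb, cb in keys:
            if fb == fa + 1 and ca == cb and rng.random() < 0.5:
                edges.append(((a.id, fa, "whole"), (b.id, fb, "whole")))
    return LDGraph(k=k, nodes=nodes, edges=edges)


def make_fold(fold, coeffs):
    return FoldSelection(fold=fold, coefficients=dict(coeffs))


@pytest.fixture
def vcf_file(tmp_path):
    """Minimal VCF with het/hom-alt/missing genotypes and one multi-allelic site."""
    text = "\n".join(
        [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsA\tsB\tsC",
            "1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t0/0\t1/1",
            "1\t200\t.\tG\tC,A\t.\tPASS\t.\tGT\t0/2\t1/2\t0/0",
            "2\t300\t.\tC\tG\t.\tPASS\t.\tGT\t./.\t0/1\t0/0",
        ]
    )
    path = tmp_path / "toy.vcf"
    path.write_text(text + "\n")
    return path


@pytest.fixture
def labels_file(tmp_path):
    path = tmp_path / "labels.tsv"
    path.write_text("sA\tcase\nsB\tcase\nsC\tcontrol\n")
    return path
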