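"""Maximum-parsimony analysis of both matrices.

Real track: exact branch-and-bound on the six-taxon transcribed-data matrix.
Synthetic track: exact branch-and-bound on the fourteen-taxon stand-in
matrix (simulator output on the published topology).  Writes optimal trees,
bootstrap consensus and homoplasy indices under results/, and prints each
track's statistics next to the printed values for the supplementary-matrix
analysis.
"""

import json
from pathlib import Path

from paintphylo.characters import write_nexus, write_tsv
from paintphylo.parsimony import bootstrap, search_bnb
from paintphylo.pipeline import (
    PRINTED_PARSIMONY,
    real_track_matrix,
    reconstruction_matrix,
)

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 42


def analyse(name: str, matrix, replicates: int, starts: int) -> dict:
    res = search_bnb(matrix)
    cons, _support = bootstrap(
        matrix, replicates=replicates, seed=SEED, n_starts=starts
    )
    (OUT / f"{name}_trees.nwk").write_text(
        "".join(t.to_newick() + "\n" for t in res.optimal_trees[:50])
    )
    (OUT / f"{name}_consensus.nwk").write_text(
        cons.to_newick(include_support=True) + "\n"
    )
    stats = {
        "n_taxa": matrix.n_taxa,
        "n_characters": matrix.n_characters,
        "n_variable": int(matrix.is_variable().sum()),
        "tree_length": res.best_length,
        "n_optimal_trees": res.n_trees,
        "consistency_index": res.ci,
        "retention_index": res.ri,
        "homoplasy_index": res.hi,
    }
    print(f"[{name}] length={res.best_length}, {res.n_trees} optimal trees, "
          f"CI={res.ci:.4f}, RI={res.ri:.4f}, HI={res.hi:.4f}")
    print(f"[{name}] bootstrap consensus: {cons.to_newick(include_support=True)}")
    return stats


def main() -> None:
    OUT.mkdir(exist_ok=True)
    real = real_track_matrix()
    synth = reconstruction_matrix()
    write_nexus(synth, OUT / "synthetic_matrix.nex")
    write_tsv(synth, OUT / "synthetic_matrix.tsv")
    stats = {
        "real": analyse("real", real, replicates=1000, starts=10),
        "synthetic": analyse("synthetic", synth, replicates=200, starts=2),
        "printed_supplementary_statistics": PRINTED_PARSIMONY,
    }
    (OUT / "parsimony_stats.json").write_text(json.dumps(stats, indent=2) + "\n")
    print(f"\nprinted supplementary-matrix statistics for comparison: "
          f"{PRINTED_PARSIMONY}")
    print(f"-> {OUT/'parsimony_stats.json'}")


if __name__ == "__main__":
    main()
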