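"""File I/O and run configuration for end-to-end analyses.

The machine surface is JSON (one object per test, all parameters echoed);
the human surface is a TSV table with one row per family × component,
mirroring the usual presentation of sign / SES / p for the six standard
tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd

from .dissim import COMPONENTS, FAMILIES, HostUseMatrix
from .phylo import PhyloTree, read_newick
from .shift_test import TestResult, results_table, run_full_test

logger = logging.getLogger("hostshift")

try:
    PACKAGE_VERSION = version("hostshift")
except PackageNotFoundError:  # pragma: no cover
    PACKAGE_VERSION = "unknown"

__all__ = ["RunConfig", "read_host_matrix", "run_from_config", "write_results"]


@dataclass
class RunConfig:
    """Everything one test run needs; all fields echoed into the output."""

    insect_tree_path: str
    host_tree_path: str | None
    matrix_path: str
    out_dir: str = "."
    families: tuple[str, ...] = FAMILIES
    components: tuple[str, ...] = COMPONENTS
    mode: str = "pairwise"
    n_perm: int = 10_000
    seed: int = 1
    alpha: float = 0.05
    exclude: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.n_perm < 1:
            raise ValueError("n_perm must be ≥ 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        bad = set(self.families) - set(FAMILIES)
        if bad:
            raise ValueError(f"unknown families: {sorted(bad)}")
        bad = set(self.components) - set(COMPONENTS)
        if bad:
            raise ValueError(f"unknown components: {sorted(bad)}")
        if "unifrac" in self.families and self.host_tree_path is None:
            raise ValueError("the unifrac family requires a host tree")


def read_host_matrix(path) -> HostUseMatrix:
    """Read and validate a delimited host-use matrix, logging a summary."""
    matrix = HostUseMatrix.from_delimited(path)
    br = matrix.breadths()
    non_override = br[~matrix.override]
    logger.info(
        "host-use matrix: %d herbivores × %d hosts; breadth %d–%d, "
        "mean %.1f ± %.1f%s",
        matrix.n_herbivores,
        len(matrix.hosts),
        int(non_override.min()),
        int(non_override.max()),
        float(non_override.mean()),
        float(non_override.std(ddof=1)) if len(non_override) > 1 else 0.0,
        f"; {int(matrix.override.sum())} override taxa" if matrix.override.any() else "",
    )
    return matrix


def run_from_config(config: RunConfig) -> list[TestResult]:
    insect_tree = read_newick(config.insect_tree_path)
    host_tree = (
        read_newick(config.host_tree_path) if config.host_tree_path else None
    )
    matrix = read_host_matrix(config.matrix_path)
    return run_full_test(
        insect_tree,
        host_tree,
        matrix,
        families=config.families,
        components=config.components,
        mode=config.mode,
        n_perm=config.n_perm,
        seed=config.seed,
        exclude=config.exclude,
    )


def write_results(
    results: list[TestResult],
    out_dir,
    config: RunConfig | None = None,
    basename: str = "shift_test",
) -> tuple[Path, Path]:
    """Write TSV + JSON result files; returns their paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = results_table(results)
    cols = [
        "family",
        "component",
        "sign",
        "ses",
        "p_two_tailed",
        "observed",
        "null_mean",
        "null_sd",
        "statistic_mode",
        "n_permutations",
        "seed",
    ]
    tsv_path = out / f"{basename}.tsv"
    table[cols].to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")

    payload = {
        "package_version": PACKAGE_VERSION,
        "results": [r.to_dict() for r in results],
    }
    if config is not None:
        payload["config"] = {
            "insect_tree": str(config.insect_tree_path),
            "host_tree": str(config.host_tree_path) if config.host_tree_path else None,
            "matrix": str(config.matrix_path),
            "families": list(config.families),
            "components": list(config.components),
            "mode": config.mode,
            "n_perm": config.n_perm,
            "seed": config.seed,
            "alpha": config.alpha,
            "exclude": list(config.exclude),
        }
    json_path = out / f"{basename}.json"
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return tsv_path, json_path


def xh_pairs(distances: pd.DataFrame, dissim: pd.DataFrame) -> pd.DataFrame:
    """Long-format (pair, X, H) export for distance-vs-dissimilarity plots."""
    labs = list(distances.index)
    rows = []
    for i in range(len(labs)):
        for j in range(i + 1, len(labs)):
            rows.append(
                {
                    "herbivore_1": labs[i],
                    "herbivore_2": labs[j],
                    "phylogenetic_distance": float(distances.iat[i, j]),
                    "dissimilarity": float(dissim.loc[labs[i], labs[j]]),
                }
            )
    return pd.DataFrame(rows)
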