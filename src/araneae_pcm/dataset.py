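"""Versioned study fixtures with validating loaders.

All fixtures are plain text under ``araneae_pcm/data`` and carry a
provenance header (``#`` comment lines).  Loaders validate aggressively
and refuse silent coercion: out-of-range scores, label mismatches between
trees and tables, or malformed rate matrices raise immediately with the
offending cell named.

Provenance levels
-----------------
* printed tables (predictors, the two-species ontogeny, the PLS-spigot
  rate matrix) are transcribed verbatim;
* tree topologies and some tip states are reconstructed from figure
  descriptions (``source`` columns distinguish text-stated from
  figure-only assignments);
* the per-species response averages and the predictor rate matrices
  other than Strategy are synthetic reconstructions, flagged in their
  filenames and headers.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from araneae_pcm.treekit import PhyloTree, parse_newick, set_unit_branch_lengths, grafen_branch_lengths
from araneae_pcm.mkace import RateMatrixSpec

__all__ = [
    "load_predictors", "load_responses", "load_trait_table", "load_ontogeny",
    "load_rate_matrix", "load_tree", "load_tip_states",
    "load_predictor_tip_states", "validate_all",
]

PREDICTOR_RANGES = {
    "Strategy": {0, 1},
    "Specific": {1, 1.5, 2, 2.5, 3, 4, 4.5, 5, 5.5},
    "Silk": {1, 1.5, 2, 3, 4},
    "Type": {1, 1.5, 2, 2.5, 3, 4},
}

RATE_MATRICES = ["pls_spigot", "strategy", "specific", "silk", "type"]


def _data_path(name: str) -> Path:
    return Path(resources.files("araneae_pcm").joinpath("data", name))  # type: ignore[arg-type]


def _read_tsv(name: str, index_col: str = "species") -> pd.DataFrame:
    frame = pd.read_csv(_data_path(name), sep="\t", comment="#", keep_default_na=False)
    return frame.set_index(index_col)


def load_predictors() -> pd.DataFrame:
    """The five predictor scores for the 22 study species (printed table)."""
    frame = _read_tsv("predictors_22taxa.tsv")
    if len(frame) != 22:
        raise ValueError(f"expected 22 species, found {len(frame)}")
    for col, allowed in PREDICTOR_RANGES.items():
        bad = frame.index[~frame[col].isin(allowed)]
        if len(bad):
            raise ValueError(
                f"out-of-range {col} score for {bad[0]!r}: {frame.loc[bad[0], col]}"
            )
    if not (frame["Instar"].astype(int) == frame["Instar"]).all() or (frame["Instar"] < 2).any():
        raise ValueError("Instar must be an integer >= 2")
    return frame.drop(columns=["family"])


def load_responses() -> pd.DataFrame:
    """Per-species average spigot counts (synthetic reconstruction of the
    supplementary ontogeny dataset; exact only where the text states
    values)."""
    frame = _read_tsv("responses_22taxa.synthetic.tsv")
    if (frame < 0).any().any():
        raise ValueError("response averages must be non-negative")
    cy_cols = [c for c in frame.columns if c.startswith("Sec_") and "CY" in c]
    if cy_cols:
        raise ValueError("cylindrical-gland columns must not exist for second instars")
    return frame


def load_trait_table() -> pd.DataFrame:
    """Predictors joined with responses; the full PGLS design table."""
    pred = load_predictors()
    resp = load_responses()
    if set(pred.index) != set(resp.index):
        raise ValueError(
            f"predictor/response species mismatch: {sorted(set(pred.index) ^ set(resp.index))}"
        )
    return pred.join(resp)


def load_ontogeny() -> pd.DataFrame:
    """Instar-by-instar functional spigot counts of the two newly studied
    species (printed ontogeny table)."""
    frame = pd.read_csv(_data_path("ontogeny_dolomedes_hogna.tsv"), sep="\t", comment="#")
    key = frame[["species", "instar", "stage"]]
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0]
        raise ValueError(f"duplicate ontogeny record: {tuple(dup)}")
    counts = frame[["MAP", "PI", "mAP", "AC_PMS", "CY_PMS", "AC_PLS", "CY_PLS", "Modified"]]
    if (counts < 0).any().any() or not (counts == counts.astype(int)).all().all():
        raise ValueError("spigot counts must be non-negative integers")
    return frame


def load_rate_matrix(name: str) -> RateMatrixSpec:
    """One of the constrained allowed-transition matrices.

    ``pls_spigot`` is the printed matrix; ``strategy`` is reconstructed
    from the stated Dollo rationale; the rest are synthetic
    reconstructions (see module docstring).
    """
    if name not in RATE_MATRICES:
        raise KeyError(f"unknown rate matrix {name!r}; choose from {RATE_MATRICES}")
    frame = pd.read_csv(
        _data_path(f"rate_matrix_{name}.csv"), comment="#", keep_default_na=False
    ).set_index("state")
    labels = list(frame.columns)
    if list(frame.index) != labels:
        raise ValueError(f"rate matrix {name!r} is not square with matching labels")
    M = np.zeros((len(labels), len(labels)), dtype=int)
    for i, row_label in enumerate(labels):
        for j, col_label in enumerate(labels):
            cell = frame.loc[row_label, col_label]
            if i == j:
                continue
            if str(cell) not in {"0", "1"}:
                raise ValueError(
                    f"rate matrix {name!r}: non-binary entry {cell!r} at "
                    f"({row_label}, {col_label})"
                )
            M[i, j] = int(cell)
    return RateMatrixSpec(state_labels=labels, allowed=M)


def load_tree(name: str = "tree22", lengths: str = "grafen", power: float = 1.0) -> PhyloTree:
    """Study topology with the requested branch-length scheme.

    ``lengths='grafen'`` (default) gives the depth-1 ultrametric tree used
    in the final analyses; ``'unit'`` gives the all-branch-lengths-1
    phylogram; ``'none'`` returns the bare topology.
    """
    if name not in ("tree22", "tree27"):
        raise KeyError("name must be 'tree22' or 'tree27'")
    tree = parse_newick(_data_path(f"{name}.nwk").read_text())
    expected = 22 if name == "tree22" else 27
    if tree.n_tips != expected:
        raise ValueError(f"{name} must have {expected} tips, found {tree.n_tips}")
    if name == "tree22":
        table_species = set(load_predictors().index)
        mismatch = table_species ^ set(tree.tip_labels)
        if mismatch:
            raise ValueError(f"tree22/trait-table label mismatch: {sorted(mismatch)}")
    if lengths == "grafen":
        return grafen_branch_lengths(tree, power=power)
    if lengths == "unit":
        return set_unit_branch_lengths(tree)
    if lengths == "none":
        return tree
    raise ValueError("lengths must be 'grafen', 'unit' or 'none'")


def load_tip_states() -> pd.Series:
    """PLS-spigot state of each of the 27 ACE taxa."""
    frame = _read_tsv("tip_states_pls_27taxa.tsv")
    tree = load_tree("tree27", lengths="none")
    mismatch = set(frame.index) ^ set(tree.tip_labels)
    if mismatch:
        raise ValueError(f"tip-state/tree27 label mismatch: {sorted(mismatch)}")
    spec = load_rate_matrix("pls_spigot")
    bad = frame.index[~frame["state"].isin(spec.state_labels)]
    if len(bad):
        raise ValueError(f"unknown state for tip {bad[0]!r}: {frame.loc[bad[0], 'state']}")
    return frame["state"]


def load_predictor_tip_states(variable: str) -> pd.Series:
    """Discrete predictor states (Strategy/Specific/Silk/Type) for the 27
    ACE taxa."""
    if variable not in ("Strategy", "Specific", "Silk", "Type"):
        raise KeyError("variable must be Strategy, Specific, Silk or Type")
    frame = _read_tsv("tip_states_predictors_27taxa.tsv")
    tree = load_tree("tree27", lengths="none")
    mismatch = set(frame.index) ^ set(tree.tip_labels)
    if mismatch:
        raise ValueError(f"predictor tip-state/tree27 mismatch: {sorted(mismatch)}")
    spec = load_rate_matrix(variable.lower() if variable != "Strategy" else "strategy")
    bad = frame.index[~frame[variable].isin(spec.state_labels)]
    if len(bad):
        raise ValueError(f"unknown {variable} state for tip {bad[0]!r}")
    return frame[variable]


def validate_all() -> dict[str, str]:
    """Run every loader; return a fixture -> summary map.

    Also evaluates the soft ontogeny cross-checks (reported, not raised):
    adult-female piriform counts should not fall below second-instar
    counts, and adult-female minor-ampullate averages should follow the
    araneoid-one / non-araneoid-two rule.
    """
    report: dict[str, str] = {}
    pred = load_predictors()
    report["predictors"] = f"{len(pred)} species x {pred.shape[1]} predictors"
    resp = load_responses()
    report["responses"] = f"{len(resp)} species x {resp.shape[1]} responses (synthetic reconstruction)"
    onto = load_ontogeny()
    report["ontogeny"] = f"{len(onto)} instar records"
    for name in RATE_MATRICES:
        spec = load_rate_matrix(name)
        report[f"rate_matrix:{name}"] = f"{spec.n_states} states, {int(spec.allowed.sum())} allowed transitions"
    for name in ("tree22", "tree27"):
        tree = load_tree(name, lengths="grafen")
        assert tree.is_ultrametric(1e-9)
        report[name] = f"{tree.n_tips} tips, ultrametric depth 1"
    t22 = set(load_tree("tree22", "none").tip_labels)
    t27 = set(load_tree("tree27", "none").tip_labels)
    if not t22 < t27:
        raise ValueError("tree27 tips must be a superset of tree22 tips")
    states = load_tip_states()
    report["tip_states:pls"] = f"{len(states)} taxa, states {sorted(states.unique())}"
    for v in ("Strategy", "Specific", "Silk", "Type"):
        sv = load_predictor_tip_states(v)
        report[f"tip_states:{v}"] = f"{len(sv)} taxa, {sv.nunique()} states"
    # soft checks
    soft = []
    table = load_trait_table()
    if (table["Fem_ALS_PI"] < table["Sec_ALS_PI"]).any():
        soft.append("adult PI < second-instar PI for some species")
    araneoid = table["Fem_PMS_mAP"] == 1
    if not (table.loc[araneoid, "Fem_PMS_mAP"] == 1).all():
        soft.append("araneoid mAP rule violated")
    report["soft_checks"] = "; ".join(soft) if soft else "all passed"
    return report
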