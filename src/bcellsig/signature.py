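"""Directional gene-list overlap statistics and ligand-signature ranking.

Implements the four-step cross-species comparison between a human
disease gene list and a compendium of mouse ligand-response
signatures:

1. restrict both lists to the shared gene universe (genes present on
   both platforms, with expression filtering standing in for human
   platform presence);
2. build each ligand's signature from its fold changes at a timepoint;
3. count overlapping genes and how many move in the same direction;
4. score the overlap with the Representation Factor
   ``RF = x / (n1 * n2 / N)``, the hypergeometric tail probability, a
   one-sided sign-concordance binomial test, and (optionally) a joint
   resampling null.

A generic hypergeometric gene-set enrichment with Bonferroni
correction is provided for pathway analysis.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConfigurationError, FormatError

__all__ = [
    "DirectionalGeneList",
    "LigandCompendium",
    "HomologMap",
    "OverlapStats",
    "build_ligand_signature",
    "restrict_to_shared_universe",
    "representation_factor",
    "hypergeom_tail",
    "sign_concordance_test",
    "resample_null",
    "overlap_stats",
    "rank_ligands",
    "gene_set_enrichment",
]


@dataclass
class DirectionalGeneList:
    """Gene symbols each tagged with a direction (+1 up, -1 down)."""

    directions: pd.Series  # index: symbol (upper-case), values in {+1, -1}

    def __post_init__(self) -> None:
        s = pd.Series(self.directions)
        s.index = s.index.astype(str).str.upper()
        if s.index.has_duplicates:
            raise FormatError("duplicate symbols in directional gene list")
        vals = set(s.astype(int))
        if not vals <= {1, -1}:
            raise FormatError(f"directions must be +1/-1, got {sorted(vals)}")
        self.directions = s.astype(int)

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "DirectionalGeneList":
        return cls(pd.Series(d, dtype=int))

    @property
    def symbols(self) -> set[str]:
        return set(self.directions.index)

    def __len__(self) -> int:
        return len(self.directions)

    def restrict(self, universe: set[str]) -> "DirectionalGeneList":
        keep = self.directions.index.isin(universe)
        return DirectionalGeneList(self.directions[keep])


@dataclass
class LigandCompendium:
    """Ligand-response table: (ligand, mouse symbol, log2 fold change, timepoint)."""

    table: pd.DataFrame

    REQUIRED = ("ligand", "symbol", "log2fc", "timepoint_h")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise FormatError(f"compendium missing columns: {sorted(missing)}")
        if not np.isfinite(self.table["log2fc"].to_numpy(float)).all():
            raise FormatError("non-finite fold changes in compendium")
        dup = self.table.duplicated(["ligand", "symbol", "timepoint_h"])
        if dup.any():
            raise FormatError("duplicate (ligand, symbol, timepoint) entries")

    @property
    def ligands(self) -> list[str]:
        return sorted(self.table["ligand"].unique())

    def entries(self, ligand: str, timepoint_h: float | None = None) -> pd.DataFrame:
        t = self.table[self.table["ligand"] == ligand]
        if timepoint_h is not None:
            t = t[t["timepoint_h"] == timepoint_h]
        return t


@dataclass
class HomologMap:
    """Mouse symbol -> human symbol mapping.

    Defaults to the same-symbol-name rule (case-insensitive); explicit
    pairs override it.
    """

    pairs: dict[str, str]  # upper-cased mouse symbol -> human symbol

    def __post_init__(self) -> None:
        self.pairs = {str(m).upper(): str(h).upper() for m, h in self.pairs.items()}

    @classmethod
    def same_symbol(cls, mouse_symbols: list[str]) -> "HomologMap":
        return cls({m: str(m).upper() for m in mouse_symbols})

    def to_human(self, mouse_symbol: str) -> str | None:
        return self.pairs.get(str(mouse_symbol).upper())

    @property
    def human_symbols(self) -> set[str]:
        return set(self.pairs.values())

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class OverlapStats:
    """Overlap of two directional gene lists within a shared universe."""

    ligand: str
    N: int
    n1: int  # disease list size within universe
    n2: int  # signature size within universe
    x: int  # overlap count
    k: int  # same-direction count within the overlap
    rf: float
    p_hyper: float
    p_sign: float
    p_resample: float | None = None
    n_resamples: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.x <= min(self.n1, self.n2)):
            raise ConfigurationError("need k <= x <= min(n1, n2)")


def build_ligand_signature(
    compendium: LigandCompendium,
    ligand: str,
    fc_cutoff: float = 1.5,
    timepoint_h: float = 4.0,
) -> DirectionalGeneList:
    """Genes with |linear fold change| >= cutoff for a ligand at a timepoint.

    The cutoff is given on the linear scale (1.5 means |log2 FC| >=
    log2 1.5); the direction is the sign of the fold change.
    """
    if ligand not in set(compendium.table["ligand"]):
        raise KeyError(f"unknown ligand: {ligand!r}")
    t = compendium.entries(ligand, timepoint_h)
    if t.empty:
        raise KeyError(f"no entries for {ligand!r} at {timepoint_h} h")
    log_cut = np.log2(fc_cutoff)
    t = t[t["log2fc"].abs() >= log_cut]
    dirs = np.where(t["log2fc"] >= 0, 1, -1)
    return DirectionalGeneList(pd.Series(dirs, index=t["symbol"].str.upper().values))


def restrict_to_shared_universe(
    disease_list: DirectionalGeneList,
    signature: DirectionalGeneList,
    human_expressed: set[str] | list[str],
    homolog_map: HomologMap,
) -> tuple[DirectionalGeneList, DirectionalGeneList, int, set[str]]:
    """Map the signature to human symbols and intersect with the universe.

    The universe is the set of expressed human genes that have a
    mouse counterpart under the homolog map; both lists are restricted
    to it.  Returns the restricted lists, the universe size ``N`` and
    the universe itself.
    """
    expressed = {str(s).upper() for s in human_expressed if str(s)}
    universe = expressed & homolog_map.human_symbols
    if not universe:
        raise ConfigurationError("shared gene universe is empty")
    mapped = {}
    for mouse_sym, d in signature.directions.items():
        human = homolog_map.to_human(mouse_sym)
        if human is not None:
            mapped[human] = int(d)
    sig_h = DirectionalGeneList.from_dict(mapped).restrict(universe)
    dis = disease_list.restrict(universe)
    return dis, sig_h, len(universe), universe


def representation_factor(x: int, n1: int, n2: int, N: int) -> float:
    """Observed overlap divided by the chance expectation ``n1*n2/N``."""
    if N <= 0:
        raise ConfigurationError("universe size N must be positive")
    if not (0 <= x <= min(n1, n2) <= N):
        raise ConfigurationError("need x <= min(n1, n2) <= N")
    if x == 0:
        return 0.0
    return x * N / (n1 * n2)


def hypergeom_tail(x: int, n1: int, n2: int, N: int) -> float:
    """Upper tail P(X >= x) for X ~ Hypergeometric(N, n1, n2)."""
    if N <= 0:
        raise ConfigurationError("universe size N must be positive")
    if not (0 <= n1 <= N and 0 <= n2 <= N):
        raise ConfigurationError("list sizes must lie in [0, N]")
    if x < 0 or x > min(n1, n2):
        raise ConfigurationError("impossible overlap count")
    if x <= max(0, n1 + n2 - N):
        return 1.0
    return float(stats.hypergeom.sf(x - 1, N, n1, n2))


def sign_concordance_test(k: int, x: int) -> float:
    """One-sided binomial tail P(K >= k | x trials, p = 1/2)."""
    if not 0 <= k <= x:
        raise ConfigurationError("need 0 <= k <= x")
    if x == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, x, 0.5))


def resample_null(
    disease_list: DirectionalGeneList,
    signature: DirectionalGeneList,
    universe: set[str],
    n_resamples: int = 10_000,
    seed: int = 0,
) -> float:
    """Joint resampling p-value for overlap size and concordance.

    Draws random directional gene sets of the signature's size from
    the universe (random +/- directions) and reports the add-one
    empirical probability that a draw achieves both an overlap at
    least as large and a same-direction count at least as large as
    observed.
    """
    rng = np.random.default_rng(seed)
    uni = np.array(sorted(universe))
    dis = disease_list.restrict(universe)
    sig = signature.restrict(universe)
    x_obs, k_obs = _overlap_counts(dis, sig)
    n2 = len(sig)

    dis_dir = dis.directions.reindex(uni).fillna(0).astype(int).to_numpy()
    in_dis_arr = dis_dir != 0

    hits = 0
    for _ in range(n_resamples):
        idx = rng.choice(len(uni), size=n2, replace=False)
        overlap_mask = in_dis_arr[idx]
        x = int(overlap_mask.sum())
        if x < x_obs:
            continue
        rand_dir = np.where(rng.random(x) < 0.5, 1, -1)
        k = int((rand_dir == dis_dir[idx][overlap_mask]).sum())
        if k >= k_obs:
            hits += 1
    return (1 + hits) / (n_resamples + 1)


def _overlap_counts(
    a: DirectionalGeneList, b: DirectionalGeneList
) -> tuple[int, int]:
    common = a.directions.index.intersection(b.directions.index)
    x = len(common)
    k = int((a.directions.loc[common] == b.directions.loc[common]).sum())
    return x, k


def overlap_stats(
    disease_list: DirectionalGeneList,
    signature: DirectionalGeneList,
    universe: set[str],
    ligand: str = "",
    n_resamples: int = 0,
    seed: int = 0,
) -> OverlapStats:
    """All overlap statistics for one (disease list, signature) pair."""
    dis = disease_list.restrict(universe)
    sig = signature.restrict(universe)
    N, n1, n2 = len(universe), len(dis), len(sig)
    x, k = _overlap_counts(dis, sig)
    p_res = None
    if n_resamples > 0:
        p_res = resample_null(dis, sig, universe, n_resamples, seed)
    return OverlapStats(
        ligand=ligand,
        N=N,
        n1=n1,
        n2=n2,
        x=x,
        k=k,
        rf=representation_factor(x, n1, n2, N) if min(n1, n2) > 0 else 0.0,
        p_hyper=hypergeom_tail(x, n1, n2, N) if min(n1, n2) > 0 else 1.0,
        p_sign=sign_concordance_test(k, x),
        p_resample=p_res,
        n_resamples=n_resamples,
        seed=seed if n_resamples > 0 else None,
    )


def rank_ligands(
    disease_list: DirectionalGeneList,
    compendium: LigandCompendium,
    human_expressed: set[str] | list[str],
    homolog_map: HomologMap,
    fc_cutoff: float = 1.5,
    timepoint_h: float = 4.0,
    n_resamples: int = 0,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Score every ligand's signature against the disease list.

    Returns one row per ligand ordered by hypergeometric p, then sign
    p, then Representation Factor descending, then name.  A ligand is
    declared ``significant`` when both its hypergeometric and sign
    p-values stay below ``alpha`` after Bonferroni correction across
    the ligand panel.
    """
    ligands = compendium.ligands
    if not ligands:
        raise ConfigurationError("compendium has no ligands")
    rows = []
    for ligand in ligands:
        sig = build_ligand_signature(compendium, ligand, fc_cutoff, timepoint_h)
        dis_r, sig_r, N, universe = restrict_to_shared_universe(
            disease_list, sig, human_expressed, homolog_map
        )
        st = overlap_stats(dis_r, sig_r, universe, ligand, n_resamples, seed)
        rows.append(st)
    m = len(ligands)
    table = pd.DataFrame(
        {
            "ligand": [s.ligand for s in rows],
            "N": [s.N for s in rows],
            "n1": [s.n1 for s in rows],
            "n2": [s.n2 for s in rows],
            "overlap": [s.x for s in rows],
            "same_direction": [s.k for s in rows],
            "rf": [s.rf for s in rows],
            "p_hyper": [s.p_hyper for s in rows],
            "p_sign": [s.p_sign for s in rows],
            "p_resample": [s.p_resample for s in rows],
        }
    )
    table["p_hyper_bonf"] = np.minimum(1.0, table["p_hyper"] * m)
    table["p_sign_bonf"] = np.minimum(1.0, table["p_sign"] * m)
    table["significant"] = (table["p_hyper_bonf"] < alpha) & (
        table["p_sign_bonf"] < alpha
    )
    table = table.sort_values(
        ["p_hyper", "p_sign", "rf", "ligand"],
        ascending=[True, True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return table


def gene_set_enrichment(
    gene_list: set[str] | list[str],
    gene_sets: dict[str, list[str]],
    universe: set[str] | list[str],
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in a query list.

    Both the query and every set are intersected with the universe
    before testing.  Corrected p is ``min(1, p * n_sets)`` under
    Bonferroni.  Empty sets (after intersection) are skipped with a
    warning.  Rows come back sorted by corrected then raw p.
    """
    if correction not in ("bonferroni", "none"):
        raise ConfigurationError(f"unknown correction: {correction!r}")
    uni = {str(g).upper() for g in universe}
    query = {str(g).upper() for g in gene_list} & uni
    rows = []
    for name, members in gene_sets.items():
        members_u = {str(g).upper() for g in members} & uni
        if not members_u:
            warnings.warn(f"gene set {name!r} is empty within the universe; skipped")
            continue
        x = len(query & members_u)
        p = hypergeom_tail(x, len(query), len(members_u), len(uni))
        rows.append((name, len(members_u), x, p))
    table = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"])
    n_tested = len(table)
    factor = n_tested if correction == "bonferroni" else 1
    table["p_corrected"] = np.minimum(1.0, table["p"] * max(1, factor))
    return table.sort_values(["p_corrected", "p", "set"], kind="mergesort").reset_index(
        drop=True
    )
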