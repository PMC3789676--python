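"""Cross-dataset SNP-set overlap and genotype-call agreement.

Genotype tables produced from different platforms or calling pipelines are
merged by reference coordinate (contig, position).  Set overlap is
summarised as Venn region counts; call agreement as the percentage of
discordant calls over site/sample pairs present and non-missing in both
datasets.  Sites whose ref/alt allele pair differs between datasets are
excluded from genotype comparison (and counted), since the two tables then
disagree about what the alleles are rather than who carries them.

Two imperfect platforms with independent per-call error rates e1 and e2
are expected to show roughly e1 + e2 discordance on homozygous truth, so
~1% discordance is consistent with ~0.5% error on each side.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from gbsim.config import ConfigurationError, InputError
from gbsim.tables import (CODE_A, CODE_B, CODE_H, CODE_MISSING, GT_HET,
                          GT_HOM_ALT, GT_HOM_REF, GT_MISSING, GenotypeTable,
                          MarkerMatrix)


@dataclass
class MergedTable:
    """Union of site keys across datasets with per-dataset presence."""

    keys: pd.DataFrame                  # columns: contig, pos
    labels: list[str]
    presence: np.ndarray                # bool (n_sites, n_datasets)
    allele_conflict: np.ndarray         # bool (n_sites,)
    shared_samples: list[str]
    #: per dataset: gt matrix aligned to keys x shared_samples; -1 where
    #: the dataset lacks the site
    gt: list[np.ndarray]

    @property
    def n_datasets(self) -> int:
        return len(self.labels)


def merge_by_position(
    tables: list[GenotypeTable], labels: list[str] | None = None,
) -> MergedTable:
    """Align tables on (contig, pos) keys and the shared sample set."""
    if labels is None:
        labels = [t.provenance or f"set{i + 1}" for i, t in enumerate(tables)]
    if len(labels) != len(tables):
        raise ConfigurationError("one label per table required")

    shared_samples = list(tables[0].samples)
    for t in tables[1:]:
        shared_samples = [s for s in shared_samples if s in t.samples]

    all_keys: dict[tuple[str, int], int] = {}
    for t in tables:
        for key in t.site_keys():
            all_keys.setdefault(key, len(all_keys))
    keys = sorted(all_keys)
    key_index = {k: i for i, k in enumerate(keys)}
    n = len(keys)

    presence = np.zeros((n, len(tables)), dtype=bool)
    alleles: list[dict[int, tuple[str, str]]] = []
    gt_mats: list[np.ndarray] = []
    for di, t in enumerate(tables):
        gt = np.full((n, len(shared_samples)), GT_MISSING, dtype=np.int8)
        amap: dict[int, tuple[str, str]] = {}
        if shared_samples:
            sub = t.subset_samples(shared_samples)
        else:
            sub = t
        for row, key in enumerate(t.site_keys()):
            i = key_index[key]
            presence[i, di] = True
            amap[i] = (t.sites["ref"].iat[row], t.sites["alt"].iat[row])
            if shared_samples:
                gt[i] = sub.gt[row]
        alleles.append(amap)
        gt_mats.append(gt)

    conflict = np.zeros(n, dtype=bool)
    for i in range(n):
        seen = {alleles[di][i] for di in range(len(tables))
                if i in alleles[di]}
        if len(seen) > 1:
            conflict[i] = True

    return MergedTable(
        pd.DataFrame(keys, columns=["contig", "pos"]),
        labels, presence, conflict, shared_samples, gt_mats)


def venn_counts(merged: MergedTable) -> dict[tuple[bool, ...], int]:
    """Counts of every presence-pattern region; regions sum to |union|."""
    if not (2 <= merged.n_datasets <= 3):
        raise ConfigurationError("venn counts support 2 or 3 datasets only")
    patterns = {}
    for row in merged.presence:
        key = tuple(bool(x) for x in row)
        patterns[key] = patterns.get(key, 0) + 1
    # make sure every non-empty pattern key exists
    from itertools import product
    for key in product((False, True), repeat=merged.n_datasets):
        if any(key):
            patterns.setdefault(key, 0)
    patterns.pop(tuple([False] * merged.n_datasets), None)
    return patterns


@dataclass
class DiscordanceReport:
    set_x: str
    set_y: str
    shared_snps: int
    shared_samples: int
    compared_calls: int
    discordant_calls: int

    @property
    def percent_discordant(self) -> float | None:
        if self.compared_calls == 0:
            return None
        return 100.0 * self.discordant_calls / self.compared_calls

    def as_dict(self) -> dict:
        return {
            "set_x": self.set_x, "set_y": self.set_y,
            "shared_snps": self.shared_snps,
            "shared_samples": self.shared_samples,
            "compared_calls": self.compared_calls,
            "discordant_calls": self.discordant_calls,
            "percent_discordant": self.percent_discordant,
        }


def percent_discordant(
    merged: MergedTable, dataset_x: int | str = 0, dataset_y: int | str = 1,
) -> DiscordanceReport:
    """Genotype disagreement over sites and samples shared by two datasets.

    Only call pairs with both calls non-missing are compared; a het-vs-hom
    difference counts as discordant.  Symmetric in its two arguments.
    """
    ix = merged.labels.index(dataset_x) if isinstance(dataset_x, str) \
        else dataset_x
    iy = merged.labels.index(dataset_y) if isinstance(dataset_y, str) \
        else dataset_y
    shared = merged.presence[:, ix] & merged.presence[:, iy] & \
        ~merged.allele_conflict
    gx = merged.gt[ix][shared]
    gy = merged.gt[iy][shared]
    both = (gx != GT_MISSING) & (gy != GT_MISSING)
    compared = int(both.sum())
    discordant = int(((gx != gy) & both).sum())
    return DiscordanceReport(
        merged.labels[ix], merged.labels[iy], int(shared.sum()),
        len(merged.shared_samples), compared, discordant)


def all_pairwise_discordance(merged: MergedTable) -> list[DiscordanceReport]:
    return [percent_discordant(merged, i, j)
            for i, j in combinations(range(merged.n_datasets), 2)]


def encode_parental(
    table: GenotypeTable, parent_a_id: str, parent_b_id: str,
) -> MarkerMatrix:
    """Re-express RIL calls as parent-of-origin codes (A/B/H).

    A site is encodable only where both parents are non-missing, homozygous
    and different; other sites are dropped.  RIL calls matching parent A
    become A, matching parent B become B, heterozygous calls H, anything
    else missing.
    """
    for pid in (parent_a_id, parent_b_id):
        if pid not in table.samples:
            raise InputError(f"parent sample {pid!r} not in table")
    pa = table.gt[:, table.samples.index(parent_a_id)]
    pb = table.gt[:, table.samples.index(parent_b_id)]
    hom = lambda g: (g == GT_HOM_REF) | (g == GT_HOM_ALT)  # noqa: E731
    usable = hom(pa) & hom(pb) & (pa != pb)

    ril_samples = [s for s in table.samples
                   if s not in (parent_a_id, parent_b_id)]
    idx = [table.samples.index(s) for s in ril_samples]
    gt = table.gt[np.ix_(usable, idx)]
    pa_u = pa[usable][:, None]
    pb_u = pb[usable][:, None]
    out = np.full(gt.shape, CODE_MISSING, dtype=np.int8)
    out[gt == pa_u] = CODE_A
    out[gt == pb_u] = CODE_B
    out[gt == GT_HET] = CODE_H

    sites = table.sites.loc[usable]
    ids = np.array([f"{c}_{p}" for c, p in
                    zip(sites["contig"], sites["pos"])])
    return MarkerMatrix(ids, out, ril_samples,
                        contig=sites["contig"].to_numpy(),
                        pos=sites["pos"].to_numpy())
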