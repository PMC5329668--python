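"""Independent brute-force reference implementations used only by tests.

Each function recomputes a pipeline quantity straight from its definition
(exhaustive enumeration, literal set algebra, sort-based quantiles) without
going through the package's optimized code paths.
"""

from __future__ import annotations

import math
from itertools import product

from epimatch.engines import generate_peptides
from epimatch.nomenclature import LOCI, project_allele


def brute_force_candidates(phenotype, table, smap, scheme, hw_factor=False):
    """All candidate genotype pairs under one linkage scheme, by exhaustion.

    Enumerates every allele-vector buildable from the scheme's block
    marginals, then every unordered vector pair, filtering by exact
    projection onto the phenotype.  Returns {canonical unordered vector
    pair: absolute frequency}.
    """
    covered = [l for l in LOCI if l in phenotype.loci]

    # Block marginals by direct summation over the table.
    marginals = []
    for block in scheme.blocks:
        idx = [LOCI.index(l) for l in block]
        marg = {}
        for h in table.entries:
            key = tuple(h.alleles[i] for i in idx)
            marg[key] = marg.get(key, 0.0) + h.frequency
        marginals.append((block, marg))

    # Every full vector buildable from one partial per block.
    vectors = []
    for combo in product(*(list(m.items()) for _, m in marginals)):
        by_locus = {}
        freq = 1.0
        for (block, _), (alleles, f) in zip(marginals, combo):
            freq *= f
            for locus, allele in zip(block, alleles):
                by_locus[locus] = allele
        vectors.append((tuple(by_locus[l] for l in LOCI), freq))

    def projection(vec):
        return tuple(
            project_allele(vec[LOCI.index(l)], phenotype.kind_at(l), smap)
            for l in covered
        )

    # Sound pruning of the projection filter: a vector whose own projection
    # leaves the phenotype's value set at any covered locus can never be part
    # of a pair whose joint projection reproduces the phenotype.
    wanted = {l: set(phenotype.values_at(l)) for l in covered}
    kept = [
        (v, f)
        for v, f in vectors
        if all(p in wanted[l] for p, l in zip(projection(v), covered))
    ]
    vectors = kept
    projections = [projection(v) for v, _ in vectors]
    out = {}
    for i in range(len(vectors)):
        v1, f1 = vectors[i]
        p1 = projections[i]
        for j in range(i, len(vectors)):
            v2, f2 = vectors[j]
            p2 = projections[j]
            ok = True
            for a, b, l in zip(p1, p2, covered):
                if {a, b} != set(phenotype.values_at(l)):
                    ok = False
                    break
            if not ok:
                continue
            freq = f1 * f2
            if hw_factor and v1 != v2:
                freq *= 2.0
            key = (v1, v2) if v1 <= v2 else (v2, v1)
            out[key] = out.get(key, 0.0) + freq
    return out


def brute_force_matches(alleles_by_locus, phenotype, smap):
    """Membership test done by expanding each phenotype value first."""
    for locus, allele in alleles_by_locus.items():
        if locus not in phenotype.loci:
            continue
        kind = phenotype.kind_at(locus)
        hit = False
        for value in phenotype.values_at(locus):
            if project_allele(allele, kind, smap) == value:
                hit = True
                break
        if not hit:
            return False
    return True


def brute_force_eplets(donor, recipient, registry, per_class=False):
    """Literal set algebra over per-allele annotation lists."""
    if per_class:
        class_i = ("A", "B", "C")
        total = set()
        for group in (class_i, ("DRB1", "DQB1")):
            d, r = set(), set()
            for a in donor.alleles:
                if a.locus in group:
                    d |= set(registry.annotations[a])
            for a in recipient.alleles:
                if a.locus in group:
                    r |= set(registry.annotations[a])
            total |= d - r
        return total
    d, r = set(), set()
    for a in donor.alleles:
        d |= set(registry.annotations[a])
    for a in recipient.alleles:
        r |= set(registry.annotations[a])
    return d - r


def brute_force_pirche2(donor, recipient, proteins, predictor, threshold=1000.0, window=15):
    """Straight-line reimplementation of the PIRCHE-II pipeline."""
    recipient_allele_list = list(recipient.alleles)
    mismatched = []
    for a in donor.alleles:
        if a not in recipient_allele_list and a not in mismatched:
            mismatched.append(a)
    drb1_list = []
    for a in recipient.alleles_at("DRB1"):
        if a not in drb1_list:
            drb1_list.append(a)
    self_proteins = []
    for a in recipient_allele_list:
        seq = proteins.sequences[a]
        if seq not in self_proteins:
            self_proteins.append(seq)
    cores = set()
    for a in mismatched:
        seq = proteins.sequences[a]
        for pep in generate_peptides(seq, window=window):
            for d in drb1_list:
                pred = predictor(pep, d)
                if pred.ic50 >= threshold:
                    continue
                in_self = False
                for s in self_proteins:
                    if pred.core in s:
                        in_self = True
                if in_self:
                    continue
                cores.add(pred.core)
    return cores


def brute_force_weighted(donor_candidates, recipient_candidates, score_fn):
    """Independently coded double loop over candidate cross products."""
    total = 0.0
    for d in donor_candidates:
        for r in recipient_candidates:
            total += d.weight * r.weight * score_fn(d.genotype, r.genotype)
    return total


def sort_quantile(values, q):
    """Linear-interpolation quantile computed from first principles."""
    xs = sorted(values)
    if not xs:
        raise ValueError("empty")
    h = (len(xs) - 1) * q
    lo = math.floor(h)
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def sort_spread(values, level):
    return (
        sort_quantile(values, (50.0 - level / 2.0) / 100.0),
        sort_quantile(values, (50.0 + level / 2.0) / 100.0),
    )
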