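"""Independent brute-force oracles, kept deliberately naive.

These re-derive expected results by direct enumeration and must stay
decoupled from the package implementations they check.
"""

from __future__ import annotations


STOPS = ("TAA", "TAG", "TGA")

CODON_TABLE = {}


def _codon_table():
    if not CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        CODON_TABLE.update(standard_dna_table.forward_table)
    return CODON_TABLE


def orf_scan_bruteforce(seq: str, min_nt: int = 91):
    """Exhaustive 3-frame scan: every maximal stop-free codon run >= min_nt.

    Returns a set of (frame, start, end, aa) tuples.
    """
    seq = seq.upper()
    table = _codon_table()
    out = set()
    for frame in range(3):
        codon_starts = list(range(frame, len(seq) - 2, 3))
        is_stop = [seq[i : i + 3] in STOPS for i in codon_starts]
        i = 0
        while i < len(codon_starts):
            if is_stop[i]:
                i += 1
                continue
            j = i
            while j < len(codon_starts) and not is_stop[j]:
                j += 1
            start = codon_starts[i]
            end = codon_starts[j - 1] + 3
            if end - start >= min_nt:
                aa = "".join(
                    "X" if "N" in seq[k : k + 3] else table.get(seq[k : k + 3], "X")
                    for k in codon_starts[i:j]
                )
                out.add((frame, start, end, aa))
            i = j
    return out


def splice_events_bruteforce(exons_a, exons_b, strand):
    """All (label, witness-coords) pairs between two exon chains.

    Exons are sorted (start, end) half-open tuples on one strand. Applies the
    documented definitions literally, via flat loops.
    """
    out = set()
    introns_a = [(exons_a[i][1], exons_a[i + 1][0]) for i in range(len(exons_a) - 1)]
    introns_b = [(exons_b[i][1], exons_b[i + 1][0]) for i in range(len(exons_b) - 1)]

    def ovl(x, y):
        return x[0] < y[1] and y[0] < x[1]

    # A5SS / A3SS
    for i, ia in enumerate(introns_a):
        for j, ib in enumerate(introns_b):
            if ia == ib:
                continue
            if strand == "+":
                donor_a, acc_a, donor_b, acc_b = ia[0], ia[1], ib[0], ib[1]
                dex_a, dex_b = exons_a[i], exons_b[j]
                aex_a, aex_b = exons_a[i + 1], exons_b[j + 1]
            else:
                donor_a, acc_a, donor_b, acc_b = ia[1], ia[0], ib[1], ib[0]
                dex_a, dex_b = exons_a[i + 1], exons_b[j + 1]
                aex_a, aex_b = exons_a[i], exons_b[j]
            if acc_a == acc_b and donor_a != donor_b and ovl(dex_a, dex_b):
                out.add(("A5SS", tuple(sorted((ia, ib)))))
            if donor_a == donor_b and acc_a != acc_b and ovl(aex_a, aex_b):
                out.add(("A3SS", tuple(sorted((ia, ib)))))

    # EXON_SKIP
    for exons, introns, other_introns in (
        (exons_a, introns_a, introns_b),
        (exons_b, introns_b, introns_a),
    ):
        for k in range(1, len(exons) - 1):
            outer = (introns[k - 1][0], introns[k][1])
            if outer in other_introns:
                out.add(("EXON_SKIP", (exons[k],)))

    # INTRON_RETENTION
    for introns, exons_other, exons_self in (
        (introns_a, exons_b, exons_a),
        (introns_b, exons_a, exons_b),
    ):
        for s, e in introns:
            for x1, x2 in exons_other:
                if x1 <= s and e <= x2:
                    if (x1, s) in exons_self and (e, x2) in exons_self:
                        out.add(("INTRON_RETENTION", ((s, e),)))

    # MXE
    for i in range(1, len(exons_a) - 1):
        for j in range(1, len(exons_b) - 1):
            if ovl(exons_a[i], exons_b[j]):
                continue
            if introns_a[i - 1][0] == introns_b[j - 1][0] and introns_a[i][1] == introns_b[j][1]:
                out.add(("MXE", tuple(sorted((exons_a[i], exons_b[j])))))

    # AFE / ALE
    if len(exons_a) >= 2 and len(exons_b) >= 2:
        if strand == "+":
            first_a, first_b = exons_a[0], exons_b[0]
            last_a, last_b = exons_a[-1], exons_b[-1]
            first_acc_a, first_acc_b = introns_a[0][1], introns_b[0][1]
            last_don_a, last_don_b = introns_a[-1][0], introns_b[-1][0]
        else:
            first_a, first_b = exons_a[-1], exons_b[-1]
            last_a, last_b = exons_a[0], exons_b[0]
            first_acc_a, first_acc_b = introns_a[-1][0], introns_b[-1][0]
            last_don_a, last_don_b = introns_a[0][1], introns_b[0][1]
        if not ovl(first_a, first_b) and first_acc_a == first_acc_b:
            out.add(("AFE", tuple(sorted((first_a, first_b)))))
        if not ovl(last_a, last_b) and last_don_a == last_don_b:
            out.add(("ALE", tuple(sorted((last_a, last_b)))))

    return out


def inference_bruteforce(protein_peptides, sequences):
    """Parsimony inference by explicit pairwise subset checks.

    ``protein_peptides``: dict protein id -> set of peptides. Returns a set
    of (kind, frozenset members, frozenset peptides).
    """
    survivors = []
    for pid, peps in protein_peptides.items():
        subsumed = False
        for other, opeps in protein_peptides.items():
            if other != pid and peps < opeps:
                subsumed = True
        if not subsumed:
            survivors.append(pid)

    groups = []
    used = set()
    for pid in sorted(survivors):
        if pid in used:
            continue
        members = [
            q
            for q in sorted(survivors)
            if protein_peptides[q] == protein_peptides[pid]
        ]
        used.update(members)
        groups.append(members)

    def trim(seq):
        i = seq.find("M")
        return seq[i:] if i >= 0 else seq

    out = set()
    for members in groups:
        if len(members) == 1:
            kind = "unique"
        elif len({trim(sequences[m]) for m in members}) == 1:
            kind = "group_identical"
        else:
            kind = "group_distinct"
        out.add(
            (kind, frozenset(members), frozenset(protein_peptides[members[0]]))
        )
    return out


def random_exon_chain(rng, max_exons=4, grid=10, span=40):
    """A random sorted exon chain on a coarse coordinate grid."""
    n = int(rng.integers(1, max_exons + 1))
    bounds = sorted(rng.choice(span, size=2 * n, replace=False))
    return [
        (int(bounds[2 * i]) * grid, int(bounds[2 * i + 1]) * grid) for i in range(n)
    ]
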