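"""Independent brute-force oracles used only by the tests.

Deliberately written with plain strings and loops, sharing no code with
the package's vectorized implementations.
"""

from __future__ import annotations

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}


def oracle_pair(a: str, b: str) -> str:
    if (a, b) in _WC:
        return "WC"
    if (a, b) in _GU:
        return "GU"
    return "MM"


def oracle_scan(
    guide: str,
    rrna: str,
    min_run: int = 9,
    max_mm: int = 1,
    max_gu: int = 2,
    relaxed: bool = False,
    relaxed_max_mm: int = 1,
    run_counts_gu: bool = True,
) -> list[dict]:
    """Enumerate every window, classify pairs, apply the rules.

    Guide position i (1-based, 5'->3') pairs with window position L-i+1;
    the +5 guide nucleotide is at position L-5 and its partner is the
    methylation site.  The +5 column bridges the consecutive-pairing run
    regardless of its own class.
    """
    L = len(guide)
    p5 = L - 5          # 1-based guide position of the +5 nucleotide
    si = p5 - 1         # 0-based
    hits = []
    for start in range(1, len(rrna) - L + 2):
        window = rrna[start - 1 : start - 1 + L]
        classes = [oracle_pair(guide[i], window[L - 1 - i]) for i in range(L)]
        n_mm = classes.count("MM")
        n_gu = classes.count("GU")

        def ok(j: int) -> bool:
            if j == si:
                return True
            if classes[j] == "WC":
                return True
            return relaxed and run_counts_gu and classes[j] == "GU"

        lo = si
        while lo > 0 and ok(lo - 1):
            lo -= 1
        hi = si
        while hi < L - 1 and ok(hi + 1):
            hi += 1
        run = hi - lo + 1
        if relaxed:
            significant = run >= min_run and n_mm <= relaxed_max_mm
        else:
            significant = run >= min_run and n_mm <= max_mm and n_gu <= max_gu
        if significant:
            hits.append(
                {
                    "target_start": start,
                    "site": start + (L - p5),
                    "site_class": classes[si],
                    "wc_run": run,
                    "n_mm": n_mm,
                    "n_gu": n_gu,
                    "productive": classes[si] == "WC",
                }
            )
    return hits


def oracle_box_windows(seq: str, consensus: str, max_mm: int) -> list[tuple[int, int]]:
    """All (start, mismatches) of consensus-like windows, brute force."""
    sets = {"R": "AG", "A": "A", "C": "C", "G": "G", "U": "U"}
    k = len(consensus)
    out = []
    for i in range(len(seq) - k + 1):
        mm = sum(
            1 for j in range(k) if seq[i + j] not in sets[consensus[j]]
        )
        if mm <= max_mm:
            out.append((i + 1, mm))
    return out
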