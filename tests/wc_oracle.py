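"""Independent scalar transcription of the Weir & Cockerham (1984)
variance components, written as plain loops over populations.  Kept
deliberately separate from (and structured differently to) the package
implementation so it can serve as an oracle."""


def wc_oracle(n, p, h):
    """n, p, h: per-population sample sizes, reference-allele frequencies
    and observed heterozygote proportions (plain lists).  Returns (a, b, c)."""
    r = len(n)
    nbar = sum(n) / r
    sum_n = sum(n)
    nc = (sum_n - sum(ni * ni for ni in n) / sum_n) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / sum_n
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / sum_n

    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1.0)) * (pbar * (1 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - ((r - 1.0) / r) * s2 - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
    )
    c = hbar / 2.0
    return a, b, c
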