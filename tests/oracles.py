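"""Independent test oracles, deliberately implemented with different machinery
than the code paths they check."""

from __future__ import annotations

from fractions import Fraction


def recoverable_cells(redacted: list[list[bool]], nrows: int, ncols: int) -> list[tuple[int, int]]:
    """Redacted cells of a (nrows+1) x (ncols+1) count table with margins that an
    adversary can recover by linear combination of visible cells and totals.

    Exact rational Gauss-Jordan elimination over the margin equations; a cell
    is recoverable iff some reduced equation pins it alone. Independent of the
    float null-space guard inside the suppression code.
    """
    unknowns = [(r, c) for r in range(nrows + 1) for c in range(ncols + 1) if redacted[r][c]]
    if not unknowns:
        return []
    index = {u: i for i, u in enumerate(unknowns)}
    equations: list[list[Fraction]] = []
    for r in range(nrows + 1):  # every row, margins included, sums into its total
        coeff = [Fraction(0)] * len(unknowns)
        touched = False
        for c in range(ncols):
            if redacted[r][c]:
                coeff[index[(r, c)]] += 1
                touched = True
        if redacted[r][ncols]:
            coeff[index[(r, ncols)]] -= 1
            touched = True
        if touched:
            equations.append(coeff)
    for c in range(ncols + 1):
        coeff = [Fraction(0)] * len(unknowns)
        touched = False
        for r in range(nrows):
            if redacted[r][c]:
                coeff[index[(r, c)]] += 1
                touched = True
        if redacted[nrows][c]:
            coeff[index[(nrows, c)]] -= 1
            touched = True
        if touched:
            equations.append(coeff)
    # Gauss-Jordan to reduced row echelon form
    m = [row[:] for row in equations]
    pivot_row = 0
    for col in range(len(unknowns)):
        sel = next((i for i in range(pivot_row, len(m)) if m[i][col] != 0), None)
        if sel is None:
            continue
        m[pivot_row], m[sel] = m[sel], m[pivot_row]
        inv = 1 / m[pivot_row][col]
        m[pivot_row] = [x * inv for x in m[pivot_row]]
        for i in range(len(m)):
            if i != pivot_row and m[i][col] != 0:
                factor = m[i][col]
                m[i] = [a - factor * b for a, b in zip(m[i], m[pivot_row])]
        pivot_row += 1
        if pivot_row == len(m):
            break
    out = []
    for row in m:
        nonzero = [j for j, x in enumerate(row) if x != 0]
        if len(nonzero) == 1:
            out.append(unknowns[nonzero[0]])
    return out
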