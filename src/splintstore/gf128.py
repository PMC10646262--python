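"""Arithmetic over GF(2^7) and a shortened systematic Reed-Solomon code.

The field has order 128 so that one symbol carries exactly one 7-bit ASCII
character code (0-127).  The primitive polynomial is pinned to
x^7 + x^3 + 1 (0b1000_1001) for bit-exact reproducibility; any primitive
polynomial of degree 7 would yield an information-equivalent code.

The code is used shortened: a k-symbol message plus ``nsym`` parity symbols,
with k + nsym <= 127.  With the default nsym = 2 the code corrects any single
symbol error, i.e. one corrupted character anywhere in the word.
"""

from __future__ import annotations

FIELD_ORDER = 128
PRIMITIVE_POLY = 0b1000_1001  # x^7 + x^3 + 1

# exp table doubled so products of logs never need an explicit mod
_EXP = [0] * 254
_LOG = [0] * FIELD_ORDER
_x = 1
for _i in range(127):
    _EXP[_i] = _x
    _LOG[_x] = _i
    _x <<= 1
    if _x & FIELD_ORDER:
        _x ^= PRIMITIVE_POLY
for _i in range(127, 254):
    _EXP[_i] = _EXP[_i - 127]


def gf_mul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return _EXP[_LOG[a] + _LOG[b]]


def gf_div(a: int, b: int) -> int:
    if b == 0:
        raise ZeroDivisionError("division by zero in GF(128)")
    if a == 0:
        return 0
    return _EXP[(_LOG[a] - _LOG[b]) % 127]


def gf_pow(a: int, n: int) -> int:
    if a == 0:
        return 0 if n else 1
    return _EXP[(_LOG[a] * n) % 127]


def gf_inv(a: int) -> int:
    return gf_div(1, a)


# --- polynomials: coefficient lists, highest degree first ------------------


def _poly_mul(p: list[int], q: list[int]) -> list[int]:
    out = [0] * (len(p) + len(q) - 1)
    for i, pc in enumerate(p):
        if pc == 0:
            continue
        for j, qc in enumerate(q):
            out[i + j] ^= gf_mul(pc, qc)
    return out


def _poly_eval(p: list[int], x: int) -> int:
    # Horner's rule
    y = 0
    for c in p:
        y = gf_mul(y, x) ^ c
    return y


def rs_generator_poly(nsym: int) -> list[int]:
    """Generator polynomial with roots alpha^0 .. alpha^(nsym-1)."""
    g = [1]
    for i in range(nsym):
        g = _poly_mul(g, [1, gf_pow(2, i)])
    return g


def rs_encode(msg: list[int], nsym: int = 2) -> list[int]:
    """Systematic encoding: returns ``msg`` followed by ``nsym`` parity symbols.

    Raises ValueError for symbols outside GF(128) or messages longer than the
    shortened-length bound (k + nsym <= 127).
    """
    for s in msg:
        if not 0 <= s < FIELD_ORDER:
            raise ValueError(f"symbol {s} outside GF({FIELD_ORDER})")
    if len(msg) + nsym > 127:
        raise ValueError(f"message too long: {len(msg)} + {nsym} parity > 127")
    gen = rs_generator_poly(nsym)
    # polynomial remainder of msg * x^nsym by gen
    rem = list(msg) + [0] * nsym
    for i in range(len(msg)):
        coef = rem[i]
        if coef != 0:
            for j in range(1, len(gen)):
                rem[i + j] ^= gf_mul(gen[j], coef)
    return list(msg) + rem[len(msg) :]


def _syndromes(codeword: list[int], nsym: int) -> list[int]:
    return [_poly_eval(codeword, gf_pow(2, i)) for i in range(nsym)]


def rs_decode(codeword: list[int], nsym: int = 2) -> tuple[list[int], int, bool]:
    """Decode a (possibly corrupted) systematic codeword.

    Returns ``(message, n_corrected, ok)``.  ``ok`` is False when the error
    pattern exceeds the code's correction capacity (more than nsym/2 symbol
    errors) or when correction produces an inconsistent result; the
    uncorrected message symbols are returned in that case.

    Berlekamp-Massey locates errors, Chien search finds their positions and
    Forney's formula the magnitudes.
    """
    msg_raw = codeword[:-nsym] if nsym else list(codeword)
    for s in codeword:
        if not 0 <= s < FIELD_ORDER:
            return msg_raw, 0, False
    synd = _syndromes(codeword, nsym)
    if not any(synd):
        return msg_raw, 0, True

    # Berlekamp-Massey: error locator sigma (lowest degree first here)
    sigma = [1]
    prev = [1]
    L = 0
    m = 1
    b = 1
    for n in range(nsym):
        d = synd[n]
        for i in range(1, L + 1):
            d ^= gf_mul(sigma[i], synd[n - i])
        if d == 0:
            m += 1
        elif 2 * L <= n:
            t = list(sigma)
            scale = gf_div(d, b)
            shifted = [0] * m + prev
            sigma = [
                (sigma[i] if i < len(sigma) else 0)
                ^ (gf_mul(scale, shifted[i]) if i < len(shifted) else 0)
                for i in range(max(len(sigma), len(shifted)))
            ]
            L = n + 1 - L
            prev = t
            b = d
            m = 1
        else:
            scale = gf_div(d, b)
            shifted = [0] * m + prev
            sigma = [
                (sigma[i] if i < len(sigma) else 0)
                ^ (gf_mul(scale, shifted[i]) if i < len(shifted) else 0)
                for i in range(max(len(sigma), len(shifted)))
            ]
            m += 1
    n_err = L
    if n_err * 2 > nsym or len(sigma) - 1 != n_err:
        return msg_raw, 0, False

    # Chien search over the shortened codeword positions
    n = len(codeword)
    positions = []
    for pos in range(n):
        # symbol at index pos multiplies x^(n-1-pos); root test at alpha^-j
        x_inv = gf_pow(2, -(n - 1 - pos) % 127)
        val = 0
        for i, c in enumerate(sigma):
            val ^= gf_mul(c, gf_pow(x_inv, i))
        if val == 0:
            positions.append(pos)
    if len(positions) != n_err:
        return msg_raw, 0, False

    # Forney: omega = synd * sigma mod x^nsym  (synd as poly, lowest first)
    omega = [0] * nsym
    for i in range(len(sigma)):
        for j in range(len(synd)):
            if i + j < nsym:
                omega[i + j] ^= gf_mul(sigma[i], synd[j])
    corrected = list(codeword)
    for pos in positions:
        x = gf_pow(2, (n - 1 - pos) % 127)  # locator value X_l
        x_inv = gf_inv(x)
        num = 0
        for i, c in enumerate(omega):
            num ^= gf_mul(c, gf_pow(x_inv, i))
        den = 0
        for i in range(1, len(sigma), 2):  # formal derivative, odd terms
            den ^= gf_mul(sigma[i], gf_pow(x_inv, i - 1))
        if den == 0:
            return msg_raw, 0, False
        corrected[pos] ^= gf_mul(x, gf_div(num, den))
    if any(_syndromes(corrected, nsym)):
        return msg_raw, 0, False
    return corrected[:-nsym] if nsym else corrected, len(positions), True
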