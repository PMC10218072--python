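"""QR-code fingerprint labels for varieties.

A variety's label payload is its name followed by ``chrom:pos=genotype``
pairs for the database marker loci, semicolon-separated -- a plain-text
fingerprint that can be printed on seed packets and scanned back.

The module contains a complete model-2 QR symbol encoder and decoder (byte
mode, all versions 1-40, error-correction levels L/M/Q/H, Reed-Solomon over
GF(256), standard mask selection by penalty score) plus PNG rendering via
Pillow.  Decoding operates on clean, axis-aligned renders such as the ones
this module writes: the symbol grid is recovered from the finder patterns,
format information is read with nearest-codeword matching and Reed-Solomon
error correction is applied per block, so a decoded payload is returned only
when every checksum verifies.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

# ---------------------------------------------------------------------------
# GF(256) arithmetic and Reed-Solomon codes (polynomial 0x11D, QR convention)
# ---------------------------------------------------------------------------

_GF_EXP = [0] * 512
_GF_LOG = [0] * 256
_x = 1
for _i in range(255):
    _GF_EXP[_i] = _x
    _GF_LOG[_x] = _i
    _x <<= 1
    if _x & 0x100:
        _x ^= 0x11D
for _i in range(255, 512):
    _GF_EXP[_i] = _GF_EXP[_i - 255]


def _gf_mul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return _GF_EXP[_GF_LOG[a] + _GF_LOG[b]]


def _gf_div(a: int, b: int) -> int:
    if b == 0:
        raise ZeroDivisionError
    if a == 0:
        return 0
    return _GF_EXP[(_GF_LOG[a] - _GF_LOG[b]) % 255]


def _poly_mul(p: Sequence[int], q: Sequence[int]) -> list[int]:
    out = [0] * (len(p) + len(q) - 1)
    for i, a in enumerate(p):
        for j, b in enumerate(q):
            out[i + j] ^= _gf_mul(a, b)
    return out


def _poly_eval(p: Sequence[int], x: int) -> int:
    y = 0
    for c in p:
        y = _gf_mul(y, x) ^ c
    return y


def _rs_generator(n_ecc: int) -> list[int]:
    g = [1]
    for i in range(n_ecc):
        g = _poly_mul(g, [1, _GF_EXP[i]])
    return g


def rs_encode(data: Sequence[int], n_ecc: int) -> list[int]:
    """Reed-Solomon parity bytes for a data block."""
    gen = _rs_generator(n_ecc)
    rem = list(data) + [0] * n_ecc
    for i in range(len(data)):
        coef = rem[i]
        if coef == 0:
            continue
        for j, g in enumerate(gen):
            rem[i + j] ^= _gf_mul(g, coef)
    return rem[len(data):]


class RSDecodeError(ValueError):
    """The Reed-Solomon block could not be corrected."""


def rs_correct(codeword: Sequence[int], n_ecc: int) -> list[int]:
    """Correct a (data + parity) block in place; return the data bytes.

    Uses Berlekamp-Massey for the error locator, Chien search for positions
    and Forney's formula for magnitudes; raises :class:`RSDecodeError` when
    the syndromes do not vanish after correction.
    """
    cw = list(codeword)
    syndromes = [_poly_eval(cw, _GF_EXP[i]) for i in range(n_ecc)]
    if not any(syndromes):
        return cw[: len(cw) - n_ecc]

    # Berlekamp-Massey
    sigma = [1]
    prev = [1]
    L = 0
    m = 1
    b = 1
    for n in range(n_ecc):
        d = syndromes[n]
        for i in range(1, L + 1):
            d ^= _gf_mul(sigma[i], syndromes[n - i])
        if d == 0:
            m += 1
        elif 2 * L <= n:
            t = list(sigma)
            scale = _gf_div(d, b)
            shifted = [0] * m + prev
            sigma = [
                (sigma[i] if i < len(sigma) else 0)
                ^ _gf_mul(scale, shifted[i] if i < len(shifted) else 0)
                for i in range(max(len(sigma), len(shifted)))
            ]
            L = n + 1 - L
            prev = t
            b = d
            m = 1
        else:
            shifted = [0] * m + prev
            sigma = [
                (sigma[i] if i < len(sigma) else 0)
                ^ _gf_mul(_gf_div(d, b), shifted[i] if i < len(shifted) else 0)
                for i in range(max(len(sigma), len(shifted)))
            ]
            m += 1

    # Chien search: error positions are where sigma(alpha^{-d}) = 0, with d
    # the polynomial degree of the codeword byte
    n_total = len(cw)
    degrees = []
    sigma_high_first = list(reversed(sigma))
    for pos in range(n_total):
        d = n_total - 1 - pos
        x_inv = _GF_EXP[(255 - d) % 255]
        if _poly_eval(sigma_high_first, x_inv) == 0:
            degrees.append(d)
    if len(degrees) != L or L > n_ecc // 2:
        raise RSDecodeError(f"uncorrectable block ({L} errors, {len(degrees)} located)")

    # Magnitudes: solve S_k = sum_j e_j * (alpha^{d_j})^k by Gaussian
    # elimination over GF(256) (at most n_ecc/2 unknowns)
    nerr = len(degrees)
    A = [[_GF_EXP[(degrees[j] * k) % 255] for j in range(nerr)] for k in range(nerr)]
    rhs = list(syndromes[:nerr])
    for col in range(nerr):
        pivot = next((r for r in range(col, nerr) if A[r][col]), None)
        if pivot is None:
            raise RSDecodeError("singular error-magnitude system")
        A[col], A[pivot] = A[pivot], A[col]
        rhs[col], rhs[pivot] = rhs[pivot], rhs[col]
        inv = _gf_div(1, A[col][col])
        A[col] = [_gf_mul(a, inv) for a in A[col]]
        rhs[col] = _gf_mul(rhs[col], inv)
        for r in range(nerr):
            if r != col and A[r][col]:
                factor = A[r][col]
                A[r] = [a ^ _gf_mul(factor, b) for a, b in zip(A[r], A[col])]
                rhs[r] ^= _gf_mul(factor, rhs[col])
    for j, d in enumerate(degrees):
        cw[n_total - 1 - d] ^= rhs[j]

    if any(_poly_eval(cw, _GF_EXP[i]) for i in range(n_ecc)):
        raise RSDecodeError("syndromes persist after correction")
    return cw[: len(cw) - n_ecc]


# ---------------------------------------------------------------------------
# Symbol geometry and capacity tables (ISO/IEC 18004 model 2)
# ---------------------------------------------------------------------------

_TOTAL_CODEWORDS = [
    0, 26, 44, 70, 100, 134, 172, 196, 242, 292, 346, 404, 466, 532, 581, 655,
    733, 815, 901, 991, 1085, 1156, 1258, 1364, 1474, 1588, 1706, 1828, 1921,
    2051, 2185, 2323, 2465, 2611, 2761, 2876, 3034, 3196, 3362, 3532, 3706,
]

# version -> [6, ...] alignment pattern centre coordinates
_ALIGNMENT = {
    1: [], 2: [6, 18], 3: [6, 22], 4: [6, 26], 5: [6, 30], 6: [6, 34],
    7: [6, 22, 38], 8: [6, 24, 42], 9: [6, 26, 46], 10: [6, 28, 50],
    11: [6, 30, 54], 12: [6, 32, 58], 13: [6, 34, 62], 14: [6, 26, 46, 66],
    15: [6, 26, 48, 70], 16: [6, 26, 50, 74], 17: [6, 30, 54, 78],
    18: [6, 30, 56, 82], 19: [6, 30, 58, 86], 20: [6, 34, 62, 90],
    21: [6, 28, 50, 72, 94], 22: [6, 26, 50, 74, 98], 23: [6, 30, 54, 78, 102],
    24: [6, 28, 54, 80, 106], 25: [6, 32, 58, 84, 110], 26: [6, 30, 58, 86, 114],
    27: [6, 34, 62, 90, 118], 28: [6, 26, 50, 74, 98, 122],
    29: [6, 30, 54, 78, 102, 126], 30: [6, 26, 52, 78, 104, 130],
    31: [6, 30, 56, 82, 108, 134], 32: [6, 34, 60, 86, 112, 138],
    33: [6, 30, 58, 86, 114, 142], 34: [6, 34, 62, 90, 118, 146],
    35: [6, 30, 54, 78, 102, 126, 150], 36: [6, 24, 50, 76, 102, 128, 154],
    37: [6, 28, 54, 80, 106, 132, 158], 38: [6, 32, 58, 84, 110, 136, 162],
    39: [6, 26, 54, 82, 110, 138, 166], 40: [6, 30, 58, 86, 114, 142, 170],
}

# (ec level, version) -> (ecc codewords per block, [(n_blocks, data codewords)])
_EC_BLOCKS: dict[str, dict[int, tuple[int, list[tuple[int, int]]]]] = {
    "L": {
        1: (7, [(1, 19)]), 2: (10, [(1, 34)]), 3: (15, [(1, 55)]),
        4: (20, [(1, 80)]), 5: (26, [(1, 108)]), 6: (18, [(2, 68)]),
        7: (20, [(2, 78)]), 8: (24, [(2, 97)]), 9: (30, [(2, 116)]),
        10: (18, [(2, 68), (2, 69)]), 11: (20, [(4, 81)]),
        12: (24, [(2, 92), (2, 93)]), 13: (26, [(4, 107)]),
        14: (30, [(3, 115), (1, 116)]), 15: (22, [(5, 87), (1, 88)]),
        16: (24, [(5, 98), (1, 99)]), 17: (28, [(1, 107), (5, 108)]),
        18: (30, [(5, 120), (1, 121)]), 19: (28, [(3, 113), (4, 114)]),
        20: (28, [(3, 107), (5, 108)]), 21: (28, [(4, 116), (4, 117)]),
        22: (28, [(2, 111), (7, 112)]), 23: (30, [(4, 121), (5, 122)]),
        24: (30, [(6, 117), (4, 118)]), 25: (26, [(8, 106), (4, 107)]),
        26: (28, [(10, 114), (2, 115)]), 27: (30, [(8, 122), (4, 123)]),
        28: (30, [(3, 117), (10, 118)]), 29: (30, [(7, 116), (7, 117)]),
        30: (30, [(5, 115), (10, 116)]), 31: (30, [(13, 115), (3, 116)]),
        32: (30, [(17, 115)]), 33: (30, [(17, 115), (1, 116)]),
        34: (30, [(13, 115), (6, 116)]), 35: (30, [(12, 121), (7, 122)]),
        36: (30, [(6, 121), (14, 122)]), 37: (30, [(17, 122), (4, 123)]),
        38: (30, [(4, 122), (18, 123)]), 39: (30, [(20, 117), (4, 118)]),
        40: (30, [(19, 118), (6, 119)]),
    },
    "M": {
        1: (10, [(1, 16)]), 2: (16, [(1, 28)]), 3: (26, [(1, 44)]),
        4: (18, [(2, 32)]), 5: (24, [(2, 43)]), 6: (16, [(4, 27)]),
        7: (18, [(4, 31)]), 8: (22, [(2, 38), (2, 39)]),
        9: (22, [(3, 36), (2, 37)]), 10: (26, [(4, 43), (1, 44)]),
        11: (30, [(1, 50), (4, 51)]), 12: (22, [(6, 36), (2, 37)]),
        13: (22, [(8, 37), (1, 38)]), 14: (24, [(4, 40), (5, 41)]),
        15: (24, [(5, 41), (5, 42)]), 16: (28, [(7, 45), (3, 46)]),
        17: (28, [(10, 46), (1, 47)]), 18: (26, [(9, 43), (4, 44)]),
        19: (26, [(3, 44), (11, 45)]), 20: (26, [(3, 41), (13, 42)]),
        21: (26, [(17, 42)]), 22: (28, [(17, 46)]),
        23: (28, [(4, 47), (14, 48)]), 24: (28, [(6, 45), (14, 46)]),
        25: (28, [(8, 47), (13, 48)]), 26: (28, [(19, 46), (4, 47)]),
        27: (28, [(22, 45), (3, 46)]), 28: (28, [(3, 45), (23, 46)]),
        29: (28, [(21, 45), (7, 46)]), 30: (28, [(19, 47), (10, 48)]),
        31: (28, [(2, 46), (29, 47)]), 32: (28, [(10, 46), (23, 47)]),
        33: (28, [(14, 46), (21, 47)]), 34: (28, [(14, 46), (23, 47)]),
        35: (28, [(12, 47), (26, 48)]), 36: (28, [(6, 47), (34, 48)]),
        37: (28, [(29, 46), (14, 47)]), 38: (28, [(13, 46), (32, 47)]),
        39: (28, [(40, 47), (7, 48)]), 40: (28, [(18, 47), (31, 48)]),
    },
    "Q": {
        1: (13, [(1, 13)]), 2: (22, [(1, 22)]), 3: (18, [(2, 17)]),
        4: (26, [(2, 24)]), 5: (18, [(2, 15), (2, 16)]),
        6: (24, [(4, 19)]), 7: (18, [(2, 14), (4, 15)]),
        8: (22, [(4, 18), (2, 19)]), 9: (20, [(4, 16), (4, 17)]),
        10: (24, [(6, 19), (2, 20)]), 11: (28, [(4, 22), (4, 23)]),
        12: (26, [(4, 20), (6, 21)]), 13: (24, [(8, 20), (4, 21)]),
        14: (20, [(11, 16), (5, 17)]), 15: (30, [(5, 24), (7, 25)]),
        16: (24, [(15, 19), (2, 20)]), 17: (28, [(1, 22), (15, 23)]),
        18: (28, [(17, 22), (1, 23)]), 19: (26, [(17, 21), (4, 22)]),
        20: (30, [(15, 24), (5, 25)]), 21: (28, [(17, 22), (6, 23)]),
        22: (30, [(7, 24), (16, 25)]), 23: (30, [(11, 24), (14, 25)]),
        24: (30, [(11, 24), (16, 25)]), 25: (30, [(7, 24), (22, 25)]),
        26: (28, [(28, 22), (6, 23)]), 27: (30, [(8, 23), (26, 24)]),
        28: (30, [(4, 24), (31, 25)]), 29: (30, [(1, 23), (37, 24)]),
        30: (30, [(15, 24), (25, 25)]), 31: (30, [(42, 24), (1, 25)]),
        32: (30, [(10, 24), (35, 25)]), 33: (30, [(29, 24), (19, 25)]),
        34: (30, [(44, 24), (7, 25)]), 35: (30, [(39, 24), (14, 25)]),
        36: (30, [(46, 24), (10, 25)]), 37: (30, [(49, 24), (10, 25)]),
        38: (30, [(48, 24), (14, 25)]), 39: (30, [(43, 24), (22, 25)]),
        40: (30, [(34, 24), (34, 25)]),
    },
    "H": {
        1: (17, [(1, 9)]), 2: (28, [(1, 16)]), 3: (22, [(2, 13)]),
        4: (16, [(4, 9)]), 5: (22, [(2, 11), (2, 12)]),
        6: (28, [(4, 15)]), 7: (26, [(4, 13), (1, 14)]),
        8: (26, [(4, 14), (2, 15)]), 9: (24, [(4, 12), (4, 13)]),
        10: (28, [(6, 15), (2, 16)]), 11: (24, [(3, 12), (8, 13)]),
        12: (28, [(7, 14), (4, 15)]), 13: (22, [(12, 11), (4, 12)]),
        14: (24, [(11, 12), (5, 13)]), 15: (24, [(11, 12), (7, 13)]),
        16: (30, [(3, 15), (13, 16)]), 17: (28, [(2, 14), (17, 15)]),
        18: (28, [(2, 14), (19, 15)]), 19: (26, [(9, 13), (16, 14)]),
        20: (28, [(15, 15), (10, 16)]), 21: (30, [(19, 16), (6, 17)]),
        22: (24, [(34, 13)]), 23: (30, [(16, 15), (14, 16)]),
        24: (30, [(30, 16), (2, 17)]), 25: (30, [(22, 15), (13, 16)]),
        26: (30, [(33, 16), (4, 17)]), 27: (30, [(12, 15), (28, 16)]),
        28: (30, [(11, 15), (31, 16)]), 29: (30, [(19, 15), (26, 16)]),
        30: (30, [(23, 15), (25, 16)]), 31: (30, [(23, 15), (28, 16)]),
        32: (30, [(19, 15), (35, 16)]), 33: (30, [(11, 15), (46, 16)]),
        34: (30, [(59, 16), (1, 17)]), 35: (30, [(22, 15), (41, 16)]),
        36: (30, [(2, 15), (64, 16)]), 37: (30, [(24, 15), (46, 16)]),
        38: (30, [(42, 15), (32, 16)]), 39: (30, [(10, 15), (67, 16)]),
        40: (30, [(20, 15), (61, 16)]),
    },
}

_EC_BITS = {"L": 0b01, "M": 0b00, "Q": 0b11, "H": 0b10}
_EC_FROM_BITS = {v: k for k, v in _EC_BITS.items()}


class QREncodeError(ValueError):
    pass


class QRDecodeError(ValueError):
    pass


def _data_capacity(version: int, ec_level: str) -> int:
    ecc, blocks = _EC_BLOCKS[ec_level][version]
    return sum(n * d for n, d in blocks)


def _char_count_bits(version: int) -> int:
    return 8 if version <= 9 else 16  # byte mode


def _choose_version(n_bytes: int, ec_level: str) -> int:
    for v in range(1, 41):
        bits = 4 + _char_count_bits(v) + 8 * n_bytes
        if bits <= 8 * _data_capacity(v, ec_level):
            return v
    raise QREncodeError(f"payload of {n_bytes} bytes exceeds QR capacity at level {ec_level}")


# -- BCH-protected metadata --------------------------------------------------

_FORMAT_MASK = 0x5412


def _bch_format(data5: int) -> int:
    v = data5 << 10
    g = 0x537
    for i in range(14, 9, -1):
        if v & (1 << i):
            v ^= g << (i - 10)
    return ((data5 << 10) | v) ^ _FORMAT_MASK


def _bch_version(version: int) -> int:
    v = version << 12
    g = 0x1F25
    for i in range(17, 11, -1):
        if v & (1 << i):
            v ^= g << (i - 12)
    return (version << 12) | v


_ALL_FORMATS = {
    _bch_format((_EC_BITS[ec] << 3) | mask): (ec, mask)
    for ec in "LMQH"
    for mask in range(8)
}


def _format_positions(size: int) -> tuple[list, list]:
    copy1 = [
        (8, 0), (8, 1), (8, 2), (8, 3), (8, 4), (8, 5), (8, 7), (8, 8),
        (7, 8), (5, 8), (4, 8), (3, 8), (2, 8), (1, 8), (0, 8),
    ]
    copy2 = [(size - 1, 8), (size - 2, 8), (size - 3, 8), (size - 4, 8),
             (size - 5, 8), (size - 6, 8), (size - 7, 8),
             (8, size - 8), (8, size - 7), (8, size - 6), (8, size - 5),
             (8, size - 4), (8, size - 3), (8, size - 2), (8, size - 1)]
    return copy1, copy2


# -- module layout -----------------------------------------------------------


def _build_function_patterns(version: int):
    """Matrix of function modules and a boolean map of reserved positions."""
    size = 17 + 4 * version
    mat = np.zeros((size, size), dtype=np.uint8)
    func = np.zeros((size, size), dtype=bool)

    def put(r, c, v):
        mat[r, c] = v
        func[r, c] = True

    def finder(r0, c0):
        for dr in range(-1, 8):
            for dc in range(-1, 8):
                r, c = r0 + dr, c0 + dc
                if not (0 <= r < size and 0 <= c < size):
                    continue
                inside = 0 <= dr <= 6 and 0 <= dc <= 6
                if inside and (dr in (0, 6) or dc in (0, 6) or (2 <= dr <= 4 and 2 <= dc <= 4)):
                    put(r, c, 1)
                else:
                    put(r, c, 0)

    finder(0, 0)
    finder(0, size - 7)
    finder(size - 7, 0)

    for i in range(8, size - 8):
        v = 1 if i % 2 == 0 else 0
        if not func[6, i]:
            put(6, i, v)
        if not func[i, 6]:
            put(i, 6, v)

    centres = _ALIGNMENT[version]
    for r0 in centres:
        for c0 in centres:
            if func[r0, c0]:
                continue  # overlaps a finder corner
            for dr in range(-2, 3):
                for dc in range(-2, 3):
                    v = 1 if max(abs(dr), abs(dc)) != 1 else 0
                    put(r0 + dr, c0 + dc, v)

    put(size - 8, 8, 1)  # dark module

    for pos in _format_positions(size):
        for r, c in pos:
            func[r, c] = True
    if version >= 7:
        for i in range(18):
            r = i % 3 + size - 11
            c = i // 3
            func[r, c] = True
            func[c, r] = True
    return mat, func


def _data_positions(size: int, func: np.ndarray) -> list[tuple[int, int]]:
    positions = []
    col = size - 1
    upward = True
    while col > 0:
        if col == 6:
            col -= 1
        rows = range(size - 1, -1, -1) if upward else range(size)
        for row in rows:
            for c in (col, col - 1):
                if not func[row, c]:
                    positions.append((row, c))
        upward = not upward
        col -= 2
    return positions


_MASK_FUNCS = (
    lambda r, c: (r + c) % 2 == 0,
    lambda r, c: r % 2 == 0,
    lambda r, c: c % 3 == 0,
    lambda r, c: (r + c) % 3 == 0,
    lambda r, c: (r // 2 + c // 3) % 2 == 0,
    lambda r, c: (r * c) % 2 + (r * c) % 3 == 0,
    lambda r, c: ((r * c) % 2 + (r * c) % 3) % 2 == 0,
    lambda r, c: ((r + c) % 2 + (r * c) % 3) % 2 == 0,
)


def _penalty(mat: np.ndarray) -> int:
    size = mat.shape[0]
    score = 0
    # rule 1: runs of >= 5 equal modules
    for axis in (0, 1):
        m = mat if axis == 0 else mat.T
        for line in m:
            run = 1
            for i in range(1, size):
                if line[i] == line[i - 1]:
                    run += 1
                else:
                    if run >= 5:
                        score += 3 + run - 5
                    run = 1
            if run >= 5:
                score += 3 + run - 5
    # rule 2: 2x2 blocks
    blocks = (
        (mat[:-1, :-1] == mat[1:, :-1])
        & (mat[:-1, :-1] == mat[:-1, 1:])
        & (mat[:-1, :-1] == mat[1:, 1:])
    )
    score += 3 * int(blocks.sum())
    # rule 3: finder-like 1:1:3:1:1 pattern with 4-module light flank
    pat1 = np.array([1, 0, 1, 1, 1, 0, 1, 0, 0, 0, 0], dtype=np.uint8)
    pat2 = pat1[::-1]
    for axis in (0, 1):
        m = mat if axis == 0 else mat.T
        for line in m:
            for i in range(size - 10):
                seg = line[i:i + 11]
                if np.array_equal(seg, pat1) or np.array_equal(seg, pat2):
                    score += 40
    # rule 4: dark-module proportion
    dark = int(mat.sum())
    pct = 100 * dark / (size * size)
    score += 10 * (int(abs(pct - 50)) // 5)
    return score


# -- encoding ----------------------------------------------------------------


def _make_codewords(payload: bytes, version: int, ec_level: str) -> list[int]:
    capacity = _data_capacity(version, ec_level)
    bits: list[int] = []

    def push(value: int, n: int) -> None:
        for i in range(n - 1, -1, -1):
            bits.append((value >> i) & 1)

    push(0b0100, 4)
    push(len(payload), _char_count_bits(version))
    for byte in payload:
        push(byte, 8)
    terminator = min(4, 8 * capacity - len(bits))
    push(0, terminator)
    while len(bits) % 8:
        bits.append(0)
    codewords = [
        int("".join(map(str, bits[i:i + 8])), 2) for i in range(0, len(bits), 8)
    ]
    pad = (0xEC, 0x11)
    i = 0
    while len(codewords) < capacity:
        codewords.append(pad[i % 2])
        i += 1
    return codewords


def _interleave(codewords: list[int], version: int, ec_level: str) -> list[int]:
    n_ecc, groups = _EC_BLOCKS[ec_level][version]
    blocks: list[list[int]] = []
    pos = 0
    for n_blocks, n_data in groups:
        for _ in range(n_blocks):
            blocks.append(codewords[pos:pos + n_data])
            pos += n_data
    ecc_blocks = [rs_encode(b, n_ecc) for b in blocks]
    out: list[int] = []
    for i in range(max(len(b) for b in blocks)):
        for b in blocks:
            if i < len(b):
                out.append(b[i])
    for i in range(n_ecc):
        for e in ecc_blocks:
            out.append(e[i])
    return out


def encode(
    payload: bytes,
    ec_level: str = "L",
    version: int | None = None,
    mask: int | None = None,
) -> np.ndarray:
    """Encode bytes into a QR module matrix (True = dark module)."""
    if ec_level not in _EC_BLOCKS:
        raise QREncodeError(f"unknown error-correction level {ec_level!r}")
    v = version if version is not None else _choose_version(len(payload), ec_level)
    if not 1 <= v <= 40:
        raise QREncodeError(f"version must be 1..40, got {v}")
    needed = 4 + _char_count_bits(v) + 8 * len(payload)
    if needed > 8 * _data_capacity(v, ec_level):
        raise QREncodeError(f"payload does not fit version {v} at level {ec_level}")

    codewords = _interleave(_make_codewords(payload, v, ec_level), v, ec_level)
    base, func = _build_function_patterns(v)
    size = base.shape[0]
    positions = _data_positions(size, func)

    bits: list[int] = []
    for cw in codewords:
        for i in range(7, -1, -1):
            bits.append((cw >> i) & 1)
    bits.extend([0] * (len(positions) - len(bits)))  # remainder bits

    def render(mask_id: int) -> np.ndarray:
        mat = base.copy()
        f = _MASK_FUNCS[mask_id]
        for bit, (r, c) in zip(bits, positions):
            mat[r, c] = bit ^ (1 if f(r, c) else 0)
        fmt = _bch_format((_EC_BITS[ec_level] << 3) | mask_id)
        copy1, copy2 = _format_positions(size)
        for i in range(15):
            bit = (fmt >> (14 - i)) & 1
            r, c = copy1[i]
            mat[r, c] = bit
            r, c = copy2[i]
            mat[r, c] = bit
        if v >= 7:
            info = _bch_version(v)
            for i in range(18):
                bit = (info >> i) & 1
                r = i % 3 + size - 11
                c = i // 3
                mat[r, c] = bit
                mat[c, r] = bit
        return mat

    if mask is not None:
        return render(mask).astype(bool)
    best = min(range(8), key=lambda k: _penalty(render(k)))
    return render(best).astype(bool)


# -- decoding ----------------------------------------------------------------


def decode(matrix: np.ndarray) -> bytes:
    """Decode a QR module matrix back to its byte payload."""
    mat = np.asarray(matrix).astype(np.uint8)
    size = mat.shape[0]
    if mat.shape[0] != mat.shape[1] or (size - 17) % 4 or not 21 <= size <= 177:
        raise QRDecodeError(f"not a QR module matrix: shape {mat.shape}")
    version = (size - 17) // 4

    copy1, copy2 = _format_positions(size)
    best = None
    for fmt, (ec, mask_id) in _ALL_FORMATS.items():
        for pos in (copy1, copy2):
            read = 0
            for r, c in pos:
                read = (read << 1) | int(mat[r, c])
            dist = bin(read ^ fmt).count("1")
            if best is None or dist < best[0]:
                best = (dist, ec, mask_id)
    dist, ec_level, mask_id = best
    if dist > 3:
        raise QRDecodeError("format information unreadable")

    _, func = _build_function_patterns(version)
    positions = _data_positions(size, func)
    f = _MASK_FUNCS[mask_id]
    bits = [int(mat[r, c]) ^ (1 if f(r, c) else 0) for r, c in positions]

    total_cw = _TOTAL_CODEWORDS[version]
    codewords = [
        int("".join(map(str, bits[i:i + 8])), 2) for i in range(0, total_cw * 8, 8)
    ]

    n_ecc, groups = _EC_BLOCKS[ec_level][version]
    sizes = [d for n, d in groups for _ in range(n)]
    n_blocks = len(sizes)
    data_blocks: list[list[int]] = [[] for _ in range(n_blocks)]
    idx = 0
    for i in range(max(sizes)):
        for b in range(n_blocks):
            if i < sizes[b]:
                data_blocks[b].append(codewords[idx])
                idx += 1
    ecc_blocks: list[list[int]] = [[] for _ in range(n_blocks)]
    for i in range(n_ecc):
        for b in range(n_blocks):
            ecc_blocks[b].append(codewords[idx])
            idx += 1

    data: list[int] = []
    for b in range(n_blocks):
        data.extend(rs_correct(data_blocks[b] + ecc_blocks[b], n_ecc))

    stream = 0
    for byte in data:
        stream = (stream << 8) | byte
    nbits = 8 * len(data)

    def take(n: int) -> int:
        nonlocal nbits
        nbits -= n
        return (stream >> nbits) & ((1 << n) - 1)

    mode = take(4)
    if mode != 0b0100:
        raise QRDecodeError(f"unsupported data mode {mode:04b} (byte mode expected)")
    count = take(_char_count_bits(version))
    if count * 8 > nbits:
        raise QRDecodeError("declared byte count exceeds available data")
    return bytes(take(8) for _ in range(count))


# -- PNG rendering -----------------------------------------------------------


def save_png(matrix: np.ndarray, path: str | Path, box_size: int = 4, border: int = 4) -> None:
    """Render a module matrix as a black-on-white PNG."""
    from PIL import Image

    mat = np.asarray(matrix, dtype=bool)
    img = np.kron(~mat, np.ones((box_size, box_size), dtype=np.uint8)) * 255
    img = np.pad(img, border * box_size, constant_values=255)
    Image.fromarray(img, mode="L").save(Path(path), format="PNG")


def load_png(path: str | Path) -> np.ndarray:
    """Recover the module matrix from a clean, axis-aligned QR PNG."""
    from PIL import Image

    arr = np.asarray(Image.open(Path(path)).convert("L")) < 128
    rows = np.flatnonzero(arr.any(axis=1))
    cols = np.flatnonzero(arr.any(axis=0))
    if len(rows) == 0:
        raise QRDecodeError("image contains no dark pixels")
    sym = arr[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    # the top-left finder's first row is 7 modules of dark: its run length
    # fixes the module pixel size
    top = sym[0]
    run = int(np.argmin(top)) if not top.all() else len(top)
    box = run // 7
    if box == 0 or sym.shape[0] % box:
        raise QRDecodeError("cannot infer module size from the image")
    size = sym.shape[0] // box
    centres = np.arange(size) * box + box // 2
    return sym[np.ix_(centres, centres)]


# -- variety payloads --------------------------------------------------------


def fingerprint_payload(db, variety: str) -> str:
    """Plain-text payload: name, then ``chrom:pos=genotype`` per marker locus."""
    vec = db.fingerprint(variety)
    parts = [variety]
    for loc, g in zip(db.marker_loci, vec):
        parts.append(f"{loc.chrom}:{loc.pos}={g if g is not None else 'NA'}")
    return ";".join(parts)


def parse_payload(text: str) -> tuple[str, list[tuple[str, int, str]]]:
    """Inverse of :func:`fingerprint_payload`."""
    parts = text.split(";")
    name = parts[0]
    markers = []
    for p in parts[1:]:
        coord, genotype = p.split("=", 1)
        chrom, pos = coord.rsplit(":", 1)
        markers.append((chrom, int(pos), genotype))
    return name, markers


def write_variety_qr(
    db, variety: str, path: str | Path, ec_level: str = "L", box_size: int = 4
) -> str:
    """Encode one variety's fingerprint payload as a QR PNG; returns the payload."""
    payload = fingerprint_payload(db, variety)
    save_png(encode(payload.encode("utf-8"), ec_level=ec_level), path, box_size=box_size)
    return payload


def read_qr_png(path: str | Path) -> str:
    """Decode a QR PNG written by :func:`write_variety_qr` back to its payload."""
    return decode(load_png(path)).decode("utf-8")
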