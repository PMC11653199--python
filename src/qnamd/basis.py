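"""Built-in Gaussian basis sets (STO-3G and 6-31G for H, C, N, O).

Only s and p shells occur in these sets, which covers the first-row
organic molecules this package targets.  Exponents and contraction
coefficients are the standard published values; coefficients refer to
normalized primitives and each contracted function is renormalized
numerically at build time.
"""

from __future__ import annotations

# Each entry: element -> list of shells (l, [exponents], [coefficients])
BASIS_SETS: dict[str, dict[str, list[tuple[int, list[float], list[float]]]]] = {
    "sto-3g": {
        "H": [
            (0, [3.42525091, 0.62391373, 0.16885540],
                [0.15432897, 0.53532814, 0.44463454]),
        ],
        "C": [
            (0, [71.6168370, 13.0450960, 3.5305122],
                [0.15432897, 0.53532814, 0.44463454]),
            (0, [2.9412494, 0.6834831, 0.2222899],
                [-0.09996723, 0.39951283, 0.70011547]),
            (1, [2.9412494, 0.6834831, 0.2222899],
                [0.15591627, 0.60768372, 0.39195739]),
        ],
        "N": [
            (0, [99.1061690, 18.0523120, 4.8856602],
                [0.15432897, 0.53532814, 0.44463454]),
            (0, [3.7804559, 0.8784966, 0.2857144],
                [-0.09996723, 0.39951283, 0.70011547]),
            (1, [3.7804559, 0.8784966, 0.2857144],
                [0.15591627, 0.60768372, 0.39195739]),
        ],
        "O": [
            (0, [130.7093200, 23.8088610, 6.4436083],
                [0.15432897, 0.53532814, 0.44463454]),
            (0, [5.0331513, 1.1695961, 0.3803890],
                [-0.09996723, 0.39951283, 0.70011547]),
            (1, [5.0331513, 1.1695961, 0.3803890],
                [0.15591627, 0.60768372, 0.39195739]),
        ],
    },
    "6-31g": {
        "H": [
            (0, [18.7311370, 2.8253937, 0.6401217],
                [0.03349460, 0.23472695, 0.81375733]),
            (0, [0.1612778], [1.0]),
        ],
        "C": [
            (0, [3047.5249, 457.36951, 103.94869, 29.210155, 9.2866630, 3.1639270],
                [0.0018347, 0.0140373, 0.0688426, 0.2321844, 0.4679413, 0.3623120]),
            (0, [7.8682724, 1.8812885, 0.5442493],
                [-0.1193324, -0.1608542, 1.1434564]),
            (1, [7.8682724, 1.8812885, 0.5442493],
                [0.0689991, 0.3164240, 0.7443083]),
            (0, [0.1687144], [1.0]),
            (1, [0.1687144], [1.0]),
        ],
        "N": [
            (0, [4173.5110, 627.45790, 142.90210, 40.234330, 12.820210, 4.3904370],
                [0.0018348, 0.0139950, 0.0685870, 0.2322410, 0.4690700, 0.3604550]),
            (0, [11.6263580, 2.7162800, 0.7722180],
                [-0.1149610, -0.1691180, 1.1458520]),
            (1, [11.6263580, 2.7162800, 0.7722180],
                [0.0675800, 0.3239070, 0.7408950]),
            (0, [0.2120313], [1.0]),
            (1, [0.2120313], [1.0]),
        ],
        "O": [
            (0, [5484.6717, 825.23495, 188.04696, 52.964500, 16.897570, 5.7996353],
                [0.0018311, 0.0139501, 0.0684451, 0.2327143, 0.4701930, 0.3585209]),
            (0, [15.5396160, 3.5999336, 1.0137618],
                [-0.1107775, -0.1480263, 1.1307670]),
            (1, [15.5396160, 3.5999336, 1.0137618],
                [0.0708743, 0.3397528, 0.7271586]),
            (0, [0.2700058], [1.0]),
            (1, [0.2700058], [1.0]),
        ],
    },
}
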