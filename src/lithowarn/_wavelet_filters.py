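"""Standard published filter banks for the supported wavelet families.

Taps are the conventional double-precision values used across wavelet
toolboxes; the dmey bank is the usual 62-tap FIR approximation of the
Meyer wavelet (only approximately orthogonal).
"""

FILTER_BANKS = {
    'haar': {
        "orthogonal": True,
        'dec_lo': [
            0.7071067811865476, 0.7071067811865476,
        ],
        'dec_hi': [
            -0.7071067811865476, 0.7071067811865476,
        ],
        'rec_lo': [
            0.7071067811865476, 0.7071067811865476,
        ],
        'rec_hi': [
            0.7071067811865476, -0.7071067811865476,
        ],
    },
    'db2': {
        "orthogonal": True,
        'dec_lo': [
            -0.12940952255126037, 0.2241438680420134, 0.8365163037378079, 0.48296291314453416,
        ],
        'dec_hi': [
            -0.48296291314453416, 0.8365163037378079, -0.2241438680420134, -0.12940952255126037,
        ],
        'rec_lo': [
            0.48296291314453416, 0.8365163037378079, 0.2241438680420134, -0.12940952255126037,
        ],
        'rec_hi': [
            -0.12940952255126037, -0.2241438680420134, 0.8365163037378079, -0.48296291314453416,
        ],
    },
    'db4': {
        "orthogonal": True,
        'dec_lo': [
            -0.010597401785069032, 0.0328830116668852, 0.030841381835560764, -0.18703481171909309,
            -0.027983769416859854, 0.6308807679298589, 0.7148465705529157, 0.2303778133088965,
        ],
        'dec_hi': [
            -0.2303778133088965, 0.7148465705529157, -0.6308807679298589, -0.027983769416859854,
            0.18703481171909309, 0.030841381835560764, -0.0328830116668852, -0.010597401785069032,
        ],
        'rec_lo': [
            0.2303778133088965, 0.7148465705529157, 0.6308807679298589, -0.027983769416859854,
            -0.18703481171909309, 0.030841381835560764, 0.0328830116668852, -0.010597401785069032,
        ],
        'rec_hi': [
            -0.010597401785069032, -0.0328830116668852, 0.030841381835560764, 0.18703481171909309,
            -0.027983769416859854, -0.6308807679298589, 0.7148465705529157, -0.2303778133088965,
        ],
    },
    'rbio2.4': {
        "orthogonal": False,
        'dec_lo': [
            0.0, 0.0, 0.0, 0.0,
            0.3535533905932738, 0.7071067811865476, 0.3535533905932738, 0.0,
            0.0, 0.0,
        ],
        'dec_hi': [
            -0.03314563036811941, -0.06629126073623882, 0.1767766952966369, 0.4198446513295126,
            -0.9943689110435825, 0.4198446513295126, 0.1767766952966369, -0.06629126073623882,
            -0.03314563036811941, 0.0,
        ],
        'rec_lo': [
            0.03314563036811941, -0.06629126073623882, -0.1767766952966369, 0.4198446513295126,
            0.9943689110435825, 0.4198446513295126, -0.1767766952966369, -0.06629126073623882,
            0.03314563036811941, 0.0,
        ],
        'rec_hi': [
            0.0, -0.0, 0.0, -0.0,
            0.3535533905932738, -0.7071067811865476, 0.3535533905932738, -0.0,
            0.0, -0.0,
        ],
    },
    'dmey': {
        "orthogonal": True,
        'dec_lo': [
            0.0, -1.009999956941423e-12, 8.519459636796214e-09, -1.111944952595278e-08,
            -1.0798819539621958e-08, 6.066975741351135e-08, -1.0866516536735883e-07, 8.200680650386481e-08,
            1.1783004497663934e-07, -5.506340565252278e-07, 1.1307947017916706e-06, -1.489549216497156e-06,
            7.367572885903746e-07, 3.20544191334478e-06, -1.6312699734552807e-05, 6.554305930575149e-05,
            -0.0006011502343516092, -0.002704672124643725, 0.002202534100911002, 0.006045814097323304,
            -0.006387718318497156, -0.011061496392513451, 0.015270015130934803, 0.017423434103729693,
            -0.03213079399021176, -0.024348745906078023, 0.0637390243228016, 0.030655091960824263,
            -0.13284520043622938, -0.035087555656258346, 0.44459300275757724, 0.7445855923188063,
            0.44459300275757724, -0.035087555656258346, -0.13284520043622938, 0.030655091960824263,
            0.0637390243228016, -0.024348745906078023, -0.03213079399021176, 0.017423434103729693,
            0.015270015130934803, -0.011061496392513451, -0.006387718318497156, 0.006045814097323304,
            0.002202534100911002, -0.002704672124643725, -0.0006011502343516092, 6.554305930575149e-05,
            -1.6312699734552807e-05, 3.20544191334478e-06, 7.367572885903746e-07, -1.489549216497156e-06,
            1.1307947017916706e-06, -5.506340565252278e-07, 1.1783004497663934e-07, 8.200680650386481e-08,
            -1.0866516536735883e-07, 6.066975741351135e-08, -1.0798819539621958e-08, -1.111944952595278e-08,
            8.519459636796214e-09, -1.009999956941423e-12,
        ],
        'dec_hi': [
            1.009999956941423e-12, 8.519459636796214e-09, 1.111944952595278e-08, -1.0798819539621958e-08,
            -6.066975741351135e-08, -1.0866516536735883e-07, -8.200680650386481e-08, 1.1783004497663934e-07,
            5.506340565252278e-07, 1.1307947017916706e-06, 1.489549216497156e-06, 7.367572885903746e-07,
            -3.20544191334478e-06, -1.6312699734552807e-05, -6.554305930575149e-05, -0.0006011502343516092,
            0.002704672124643725, 0.002202534100911002, -0.006045814097323304, -0.006387718318497156,
            0.011061496392513451, 0.015270015130934803, -0.017423434103729693, -0.03213079399021176,
            0.024348745906078023, 0.0637390243228016, -0.030655091960824263, -0.13284520043622938,
            0.035087555656258346, 0.44459300275757724, -0.7445855923188063, 0.44459300275757724,
            0.035087555656258346, -0.13284520043622938, -0.030655091960824263, 0.0637390243228016,
            0.024348745906078023, -0.03213079399021176, -0.017423434103729693, 0.015270015130934803,
            0.011061496392513451, -0.006387718318497156, -0.006045814097323304, 0.002202534100911002,
            0.002704672124643725, -0.0006011502343516092, -6.554305930575149e-05, -1.6312699734552807e-05,
            -3.20544191334478e-06, 7.367572885903746e-07, 1.489549216497156e-06, 1.1307947017916706e-06,
            5.506340565252278e-07, 1.1783004497663934e-07, -8.200680650386481e-08, -1.0866516536735883e-07,
            -6.066975741351135e-08, -1.0798819539621958e-08, 1.111944952595278e-08, 8.519459636796214e-09,
            1.009999956941423e-12, 0.0,
        ],
        'rec_lo': [
            -1.009999956941423e-12, 8.519459636796214e-09, -1.111944952595278e-08, -1.0798819539621958e-08,
            6.066975741351135e-08, -1.0866516536735883e-07, 8.200680650386481e-08, 1.1783004497663934e-07,
            -5.506340565252278e-07, 1.1307947017916706e-06, -1.489549216497156e-06, 7.367572885903746e-07,
            3.20544191334478e-06, -1.6312699734552807e-05, 6.554305930575149e-05, -0.0006011502343516092,
            -0.002704672124643725, 0.002202534100911002, 0.006045814097323304, -0.006387718318497156,
            -0.011061496392513451, 0.015270015130934803, 0.017423434103729693, -0.03213079399021176,
            -0.024348745906078023, 0.0637390243228016, 0.030655091960824263, -0.13284520043622938,
            -0.035087555656258346, 0.44459300275757724, 0.7445855923188063, 0.44459300275757724,
            -0.035087555656258346, -0.13284520043622938, 0.030655091960824263, 0.0637390243228016,
            -0.024348745906078023, -0.03213079399021176, 0.017423434103729693, 0.015270015130934803,
            -0.011061496392513451, -0.006387718318497156, 0.006045814097323304, 0.002202534100911002,
            -0.002704672124643725, -0.0006011502343516092, 6.554305930575149e-05, -1.6312699734552807e-05,
            3.20544191334478e-06, 7.367572885903746e-07, -1.489549216497156e-06, 1.1307947017916706e-06,
            -5.506340565252278e-07, 1.1783004497663934e-07, 8.200680650386481e-08, -1.0866516536735883e-07,
            6.066975741351135e-08, -1.0798819539621958e-08, -1.111944952595278e-08, 8.519459636796214e-09,
            -1.009999956941423e-12, 0.0,
        ],
        'rec_hi': [
            0.0, 1.009999956941423e-12, 8.519459636796214e-09, 1.111944952595278e-08,
            -1.0798819539621958e-08, -6.066975741351135e-08, -1.0866516536735883e-07, -8.200680650386481e-08,
            1.1783004497663934e-07, 5.506340565252278e-07, 1.1307947017916706e-06, 1.489549216497156e-06,
            7.367572885903746e-07, -3.20544191334478e-06, -1.6312699734552807e-05, -6.554305930575149e-05,
            -0.0006011502343516092, 0.002704672124643725, 0.002202534100911002, -0.006045814097323304,
            -0.006387718318497156, 0.011061496392513451, 0.015270015130934803, -0.017423434103729693,
            -0.03213079399021176, 0.024348745906078023, 0.0637390243228016, -0.030655091960824263,
            -0.13284520043622938, 0.035087555656258346, 0.44459300275757724, -0.7445855923188063,
            0.44459300275757724, 0.035087555656258346, -0.13284520043622938, -0.030655091960824263,
            0.0637390243228016, 0.024348745906078023, -0.03213079399021176, -0.017423434103729693,
            0.015270015130934803, 0.011061496392513451, -0.006387718318497156, -0.006045814097323304,
            0.002202534100911002, 0.002704672124643725, -0.0006011502343516092, -6.554305930575149e-05,
            -1.6312699734552807e-05, -3.20544191334478e-06, 7.367572885903746e-07, 1.489549216497156e-06,
            1.1307947017916706e-06, 5.506340565252278e-07, 1.1783004497663934e-07, -8.200680650386481e-08,
            -1.0866516536735883e-07, -6.066975741351135e-08, -1.0798819539621958e-08, 1.111944952595278e-08,
            8.519459636796214e-09, 1.009999956941423e-12,
        ],
    },
}
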