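"""Numba kernels for the O'Hara-Rudy (2011) human ventricular epicardial myocyte.

The right-hand side is written out from the published model formulation
(epicardial parameterization). All units follow the original model: time in
ms, voltage in mV, concentrations in mM, currents in uA/uF.

Layout conventions shared with :mod:`cardiopop.model`:

* state vector of 41 entries, ordered as in ``STATE_NAMES``;
* runtime parameter vector ``P`` of 20 entries, ordered as in ``P_*`` index
  constants below (conductance multipliers, extracellular ions, I_CaL
  steady-state gating shifts, stimulus);
* current snapshot of 16 entries ordered as in ``CURRENT_NAMES``.

Gating variables (and the relaxation-form fluxes J_rel,NP / J_rel,CaMK and
the I_CaL Ca-dependent mode fraction ``nca``) are advanced with exact
exponential (Rush-Larsen) updates; voltage, concentrations and CaMK-trapped
fraction with forward Euler on an error-adaptive step.
"""

import numpy as np
from numba import njit

NY = 41
NCUR = 16

# --- parameter vector indices -------------------------------------------------
P_INA, P_INAL, P_ICAL, P_IKR, P_IKS, P_IK1, P_ITO, P_INACA, P_INAK = range(9)
P_IKB, P_INAB, P_ICAB, P_IPCA = 9, 10, 11, 12
P_KO, P_NAO, P_CAO = 13, 14, 15
P_DVACT, P_DVINACT = 16, 17
P_STIMAMP, P_STIMDUR = 18, 19
NP = 20

# --- state indices ------------------------------------------------------------
IV, INAI, INASS, IKI, IKSS, ICAI, ICASS, ICANSR, ICAJSR = range(9)
IM, IHF, IHS, IJ, IHSP, IJP, IML, IHL, IHLP = range(9, 18)
IA, IIF, IIS, IAP, IIFP, IISP = range(18, 24)
ID, IFF, IFS, IFCAF, IFCAS, IJCA, INCA, IFFP, IFCAFP = range(24, 33)
IXRF, IXRS, IXS1, IXS2, IXK1 = range(33, 38)
IJRELNP, IJRELP, ICAMKT = 38, 39, 40

# --- current snapshot indices ---------------------------------------------------
C_INA, C_INAL, C_ITO, C_ICAL, C_ICANA, C_ICAK, C_IKR, C_IKS, C_IK1 = range(9)
C_INACA_I, C_INACA_SS, C_INAK, C_INAB, C_IKB, C_IPCA, C_ICAB = range(9, 16)

# physical constants
_R = 8314.0
_T = 310.0
_F = 96485.0

# cell geometry (epicardial; the original model uses 3.14 for pi)
_L = 0.01
_RAD = 0.0011
_VCELL = 1000.0 * 3.14 * _RAD * _RAD * _L
_AGEO = 2.0 * 3.14 * _RAD * _RAD + 2.0 * 3.14 * _RAD * _L
_ACAP = 2.0 * _AGEO
_VMYO = 0.68 * _VCELL
_VNSR = 0.0552 * _VCELL
_VJSR = 0.0048 * _VCELL
_VSS = 0.02 * _VCELL


@njit(cache=True)
def rates(y, P, istim, dy, inf, tau, cur):
    """Fill dy (full time derivatives), inf/tau (relaxation targets for the
    exponentially-updated states), and cur (current snapshot)."""
    v = y[IV]
    # guard the GHK 0/0 singularities at v == 0 with a tiny offset
    if -1e-6 < v < 1e-6:
        v = 1e-6
    nai = y[INAI]
    nass = y[INASS]
    ki = y[IKI]
    kss = y[IKSS]
    cai = y[ICAI]
    cass = y[ICASS]
    cansr = y[ICANSR]
    cajsr = y[ICAJSR]
    camkt = y[ICAMKT]

    ko = P[P_KO]
    nao = P[P_NAO]
    cao = P[P_CAO]

    # CaMK (trapping model)
    kmcamk = 0.15
    acamk = 0.05
    bcamk = 0.00068
    camko = 0.05
    kmcam = 0.0015
    camkb = camko * (1.0 - camkt) / (1.0 + kmcam / cass)
    camka = camkb + camkt
    dy[ICAMKT] = acamk * camkb * (camkb + camkt) - bcamk * camkt
    fp = 1.0 / (1.0 + kmcamk / camka)  # CaMK-phosphorylated fraction

    # reversal potentials
    rtf = _R * _T / _F
    ena = rtf * np.log(nao / nai)
    ek = rtf * np.log(ko / ki)
    pkna = 0.01833
    eks = rtf * np.log((ko + pkna * nao) / (ki + pkna * nai))
    vfrt = v / rtf
    vffrt = v * _F / rtf

    # --- INa (fast) ---
    mss = 1.0 / (1.0 + np.exp(-(v + 39.57) / 9.871))
    tm = 1.0 / (6.765 * np.exp((v + 11.64) / 34.77) + 8.552 * np.exp(-(v + 77.42) / 5.955))
    hss = 1.0 / (1.0 + np.exp((v + 82.90) / 6.086))
    thf = 1.0 / (1.432e-5 * np.exp(-(v + 1.196) / 6.285) + 6.149 * np.exp((v + 0.5096) / 20.27))
    ths = 1.0 / (0.009794 * np.exp(-(v + 17.95) / 28.05) + 0.3343 * np.exp((v + 5.730) / 56.66))
    ahf = 0.99
    ahs = 1.0 - ahf
    jss = hss
    tj = 2.038 + 1.0 / (0.02136 * np.exp(-(v + 100.6) / 8.281) + 0.3052 * np.exp((v + 0.9941) / 38.45))
    hssp = 1.0 / (1.0 + np.exp((v + 89.1) / 6.086))
    thsp = 3.0 * ths
    tjp = 1.46 * tj
    inf[IM], tau[IM] = mss, tm
    inf[IHF], tau[IHF] = hss, thf
    inf[IHS], tau[IHS] = hss, ths
    inf[IJ], tau[IJ] = jss, tj
    inf[IHSP], tau[IHSP] = hssp, thsp
    inf[IJP], tau[IJP] = jss, tjp
    h = ahf * y[IHF] + ahs * y[IHS]
    hp = ahf * y[IHF] + ahs * y[IHSP]
    gna = 75.0
    ina = P[P_INA] * gna * (v - ena) * y[IM] ** 3 * ((1.0 - fp) * h * y[IJ] + fp * hp * y[IJP])

    # --- INaL (late) ---
    mlss = 1.0 / (1.0 + np.exp(-(v + 42.85) / 5.264))
    hlss = 1.0 / (1.0 + np.exp((v + 87.61) / 7.488))
    hlssp = 1.0 / (1.0 + np.exp((v + 93.81) / 7.488))
    thl = 200.0
    inf[IML], tau[IML] = mlss, tm
    inf[IHL], tau[IHL] = hlss, thl
    inf[IHLP], tau[IHLP] = hlssp, 3.0 * thl
    gnal = 0.0075 * 0.6  # epicardial scaling
    inal = P[P_INAL] * gnal * (v - ena) * y[IML] * ((1.0 - fp) * y[IHL] + fp * y[IHLP])

    # --- Ito ---
    ass = 1.0 / (1.0 + np.exp(-(v - 14.34) / 14.82))
    ta = 1.0515 / (
        1.0 / (1.2089 * (1.0 + np.exp(-(v - 18.4099) / 29.3814)))
        + 3.5 / (1.0 + np.exp((v + 100.0) / 29.3814))
    )
    iss = 1.0 / (1.0 + np.exp((v + 43.94) / 5.711))
    delta_epi = 1.0 - 0.95 / (1.0 + np.exp((v + 70.0) / 5.0))  # epicardial
    tif = (4.562 + 1.0 / (0.3933 * np.exp(-(v + 100.0) / 100.0) + 0.08004 * np.exp((v + 50.0) / 16.59))) * delta_epi
    tis = (23.62 + 1.0 / (0.001416 * np.exp(-(v + 96.52) / 59.05) + 1.780e-8 * np.exp((v + 114.1) / 8.079))) * delta_epi
    aif = 1.0 / (1.0 + np.exp((v - 213.6) / 151.2))
    ais = 1.0 - aif
    assp = 1.0 / (1.0 + np.exp(-(v - 24.34) / 14.82))
    dti_develop = 1.354 + 1e-4 / (np.exp((v - 167.4) / 15.89) + np.exp(-(v - 12.23) / 0.2154))
    dti_recover = 1.0 - 0.5 / (1.0 + np.exp((v + 70.0) / 20.0))
    tifp = dti_develop * dti_recover * tif
    tisp = dti_develop * dti_recover * tis
    inf[IA], tau[IA] = ass, ta
    inf[IIF], tau[IIF] = iss, tif
    inf[IIS], tau[IIS] = iss, tis
    inf[IAP], tau[IAP] = assp, ta
    inf[IIFP], tau[IIFP] = iss, tifp
    inf[IISP], tau[IISP] = iss, tisp
    i_gate = aif * y[IIF] + ais * y[IIS]
    ip_gate = aif * y[IIFP] + ais * y[IISP]
    gto = 0.02 * 4.0  # epicardial scaling
    ito = P[P_ITO] * gto * (v - ek) * ((1.0 - fp) * y[IA] * i_gate + fp * y[IAP] * ip_gate)

    # --- ICaL / ICaNa / ICaK ---
    # steady-state gating shifts (window-current knob + ISO): activation
    # evaluated at v - dv_act, inactivation at v - dv_inact; time constants
    # deliberately unshifted.
    va = v - P[P_DVACT]
    vi = v - P[P_DVINACT]
    dss = 1.0 / (1.0 + np.exp(-(va + 3.940) / 4.230))
    td = 0.6 + 1.0 / (np.exp(-0.05 * (v + 6.0)) + np.exp(0.09 * (v + 14.0)))
    fss = 1.0 / (1.0 + np.exp((vi + 19.58) / 3.696))
    tff = 7.0 + 1.0 / (0.0045 * np.exp(-(v + 20.0) / 10.0) + 0.0045 * np.exp((v + 20.0) / 10.0))
    tfs = 1000.0 + 1.0 / (3.5e-5 * np.exp(-(v + 5.0) / 4.0) + 3.5e-5 * np.exp((v + 5.0) / 6.0))
    aff = 0.6
    afs = 1.0 - aff
    f = aff * y[IFF] + afs * y[IFS]
    fcass = fss
    tfcaf = 7.0 + 1.0 / (0.04 * np.exp(-(v - 4.0) / 7.0) + 0.04 * np.exp((v - 4.0) / 7.0))
    tfcas = 100.0 + 1.0 / (0.00012 * np.exp(-v / 3.0) + 0.00012 * np.exp(v / 7.0))
    afcaf = 0.3 + 0.6 / (1.0 + np.exp((v - 10.0) / 10.0))
    afcas = 1.0 - afcaf
    fca = afcaf * y[IFCAF] + afcas * y[IFCAS]
    tjca = 75.0
    ktaup = 2.5
    fp_gate = aff * y[IFFP] + afs * y[IFS]
    fcap = afcaf * y[IFCAFP] + afcas * y[IFCAS]
    inf[ID], tau[ID] = dss, td
    inf[IFF], tau[IFF] = fss, tff
    inf[IFS], tau[IFS] = fss, tfs
    inf[IFCAF], tau[IFCAF] = fcass, tfcaf
    inf[IFCAS], tau[IFCAS] = fcass, tfcas
    inf[IJCA], tau[IJCA] = fcass, tjca
    inf[IFFP], tau[IFFP] = fss, ktaup * tff
    inf[IFCAFP], tau[IFCAFP] = fcass, ktaup * tfcaf
    kmn = 0.002
    k2n = 1000.0
    km2n = y[IJCA] * 1.0
    anca = 1.0 / (k2n / km2n + (1.0 + kmn / cass) ** 4)
    # dnca = anca*k2n - nca*km2n is linear; relaxation form for the stepper
    inf[INCA], tau[INCA] = anca * k2n / km2n, 1.0 / km2n
    ex1 = np.exp(vfrt)
    ex2 = np.exp(2.0 * vfrt)
    phical = 4.0 * vffrt * (cass * ex2 - 0.341 * cao) / (ex2 - 1.0)
    phicana = 1.0 * vffrt * (0.75 * nass * ex1 - 0.75 * nao) / (ex1 - 1.0)
    phicak = 1.0 * vffrt * (0.75 * kss * ex1 - 0.75 * ko) / (ex1 - 1.0)
    pca = 0.0001 * 1.2  # epicardial scaling
    pcap = 1.1 * pca
    pcana = 0.00125 * pca
    pcak = 3.574e-4 * pca
    pcanap = 0.00125 * pcap
    pcakp = 3.574e-4 * pcap
    nca = y[INCA]
    d = y[ID]
    jca = y[IJCA]
    mode = d * (f * (1.0 - nca) + jca * fca * nca)
    modep = d * (fp_gate * (1.0 - nca) + jca * fcap * nca)
    ical = P[P_ICAL] * ((1.0 - fp) * pca * phical * mode + fp * pcap * phical * modep)
    icana = P[P_ICAL] * ((1.0 - fp) * pcana * phicana * mode + fp * pcanap * phicana * modep)
    icak = P[P_ICAL] * ((1.0 - fp) * pcak * phicak * mode + fp * pcakp * phicak * modep)

    # --- IKr ---
    xrss = 1.0 / (1.0 + np.exp(-(v + 8.337) / 6.789))
    txrf = 12.98 + 1.0 / (0.3652 * np.exp((v - 31.66) / 3.869) + 4.123e-5 * np.exp(-(v - 47.78) / 20.38))
    txrs = 1.865 + 1.0 / (0.06629 * np.exp((v - 34.70) / 7.355) + 1.128e-5 * np.exp(-(v - 29.74) / 25.94))
    axrf = 1.0 / (1.0 + np.exp((v + 54.81) / 38.21))
    axrs = 1.0 - axrf
    inf[IXRF], tau[IXRF] = xrss, txrf
    inf[IXRS], tau[IXRS] = xrss, txrs
    xr = axrf * y[IXRF] + axrs * y[IXRS]
    rkr = 1.0 / (1.0 + np.exp((v + 55.0) / 75.0)) * 1.0 / (1.0 + np.exp((v - 10.0) / 30.0))
    gkr = 0.046 * 1.3  # epicardial scaling
    ikr = P[P_IKR] * gkr * np.sqrt(ko / 5.4) * xr * rkr * (v - ek)

    # --- IKs ---
    xs1ss = 1.0 / (1.0 + np.exp(-(v + 11.60) / 8.932))
    txs1 = 817.3 + 1.0 / (2.326e-4 * np.exp((v + 48.28) / 17.80) + 0.001292 * np.exp(-(v + 210.0) / 230.0))
    txs2 = 1.0 / (0.01 * np.exp((v - 50.0) / 20.0) + 0.0193 * np.exp(-(v + 66.54) / 31.0))
    inf[IXS1], tau[IXS1] = xs1ss, txs1
    inf[IXS2], tau[IXS2] = xs1ss, txs2
    ksca = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    gks = 0.0034 * 1.4  # epicardial scaling
    iks = P[P_IKS] * gks * ksca * y[IXS1] * y[IXS2] * (v - eks)

    # --- IK1 ---
    xk1ss = 1.0 / (1.0 + np.exp(-(v + 2.5538 * ko + 144.59) / (1.5692 * ko + 3.8115)))
    txk1 = 122.2 / (np.exp(-(v + 127.2) / 20.36) + np.exp((v + 236.8) / 69.33))
    inf[IXK1], tau[IXK1] = xk1ss, txk1
    rk1 = 1.0 / (1.0 + np.exp((v + 105.8 - 2.6 * ko) / 9.493))
    gk1 = 0.1908 * 1.2  # epicardial scaling
    ik1 = P[P_IK1] * gk1 * np.sqrt(ko) * rk1 * y[IXK1] * (v - ek)

    # --- INaCa (myoplasmic and subspace components) ---
    kna1 = 15.0
    kna2 = 5.0
    kna3 = 88.12
    kasymm = 12.5
    wna = 6.0e4
    wca = 6.0e4
    wnaca = 5.0e3
    kcaon = 1.5e6
    kcaoff = 5.0e3
    qna = 0.5224
    qca = 0.1670
    hca = np.exp(qca * vfrt)
    hna = np.exp(qna * vfrt)
    # myoplasmic
    h1 = 1.0 + nai / kna3 * (1.0 + hna)
    h2 = (nai * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nai / kna1 * (1.0 + nai / kna2)
    h5 = nai * nai / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    h7 = 1.0 + nao / kna3 * (1.0 + 1.0 / hna)
    h8 = nao / (kna3 * hna * h7)
    h9 = 1.0 / h7
    h10 = kasymm + 1.0 + nao / kna1 * (1.0 + nao / kna2)
    h11 = nao * nao / (h10 * kna1 * kna2)
    h12 = 1.0 / h10
    k1 = h12 * cao * kcaon
    k2 = kcaoff
    k3p = h9 * wca
    k3pp = h8 * wnaca
    k3 = k3p + k3pp
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k5 = kcaoff
    k6 = h6 * cai * kcaon
    k7 = h5 * h2 * wna
    k8 = h8 * h11 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    e1 = x1 / (x1 + x2 + x3 + x4)
    e2 = x2 / (x1 + x2 + x3 + x4)
    e3 = x3 / (x1 + x2 + x3 + x4)
    e4 = x4 / (x1 + x2 + x3 + x4)
    kmcaact = 150.0e-6
    allo = 1.0 / (1.0 + (kmcaact / cai) ** 2)
    jncxna = 3.0 * (e4 * k7 - e1 * k8) + e3 * k4pp - e2 * k3pp
    jncxca = e2 * k2 - e1 * k1
    gncx = 0.0008 * 1.1  # epicardial scaling
    inaca_i = P[P_INACA] * 0.8 * gncx * allo * (1.0 * jncxna + 2.0 * jncxca)
    # subspace (same scheme with nass/cass)
    h1 = 1.0 + nass / kna3 * (1.0 + hna)
    h2 = (nass * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nass / kna1 * (1.0 + nass / kna2)
    h5 = nass * nass / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    k1 = h12 * cao * kcaon
    k3p = h9 * wca
    k3pp = h8 * wnaca
    k3 = k3p + k3pp
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k6 = h6 * cass * kcaon
    k7 = h5 * h2 * wna
    k8 = h8 * h11 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    e1 = x1 / (x1 + x2 + x3 + x4)
    e2 = x2 / (x1 + x2 + x3 + x4)
    e3 = x3 / (x1 + x2 + x3 + x4)
    e4 = x4 / (x1 + x2 + x3 + x4)
    allo_ss = 1.0 / (1.0 + (kmcaact / cass) ** 2)
    jncxna = 3.0 * (e4 * k7 - e1 * k8) + e3 * k4pp - e2 * k3pp
    jncxca = e2 * k2 - e1 * k1
    inaca_ss = P[P_INACA] * 0.2 * gncx * allo_ss * (1.0 * jncxna + 2.0 * jncxca)

    # --- INaK ---
    k1p = 949.5
    k1m = 182.4
    k2p = 687.2
    k2m = 39.4
    k3p = 1899.0
    k3m = 79300.0
    k4p = 639.0
    k4m = 40.0
    knai0 = 9.073
    knao0 = 27.78
    delta = -0.1550
    knai = knai0 * np.exp(delta * vfrt / 3.0)
    knao = knao0 * np.exp((1.0 - delta) * vfrt / 3.0)
    kki = 0.5
    kko = 0.3582
    mgadp = 0.05
    mgatp = 9.8
    kmgatp = 1.698e-7
    hbig = 1.0e-7
    ep = 4.2
    khp = 1.698e-7
    knap = 224.0
    kxkur = 292.0
    pbig = ep / (1.0 + hbig / khp + nai / knap + ki / kxkur)
    a1 = (k1p * (nai / knai) ** 3) / ((1.0 + nai / knai) ** 3 + (1.0 + ki / kki) ** 2 - 1.0)
    b1 = k1m * mgadp
    a2 = k2p
    b2 = (k2m * (nao / knao) ** 3) / ((1.0 + nao / knao) ** 3 + (1.0 + ko / kko) ** 2 - 1.0)
    a3 = (k3p * (ko / kko) ** 2) / ((1.0 + nao / knao) ** 3 + (1.0 + ko / kko) ** 2 - 1.0)
    b3 = (k3m * pbig * hbig) / (1.0 + mgatp / kmgatp)
    a4 = (k4p * mgatp / kmgatp) / (1.0 + mgatp / kmgatp)
    b4 = (k4m * (ki / kki) ** 2) / ((1.0 + nai / knai) ** 3 + (1.0 + ki / kki) ** 2 - 1.0)
    x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
    x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
    x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
    x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b2 * a1
    e1 = x1 / (x1 + x2 + x3 + x4)
    e2 = x2 / (x1 + x2 + x3 + x4)
    e3 = x3 / (x1 + x2 + x3 + x4)
    e4 = x4 / (x1 + x2 + x3 + x4)
    jnakna = 3.0 * (e1 * a3 - e2 * b3)
    jnakk = 2.0 * (e4 * b1 - e3 * a1)
    pnak = 30.0 * 0.9  # epicardial scaling
    inak = P[P_INAK] * pnak * (1.0 * jnakna + 1.0 * jnakk)

    # --- background and pump currents ---
    xkb = 1.0 / (1.0 + np.exp(-(v - 14.48) / 18.34))
    gkb = 0.003 * 0.6  # epicardial scaling
    ikb = P[P_IKB] * gkb * xkb * (v - ek)
    pnab = 3.75e-10
    inab = P[P_INAB] * pnab * vffrt * (nai * ex1 - nao) / (ex1 - 1.0)
    pcab = 2.5e-8
    icab = P[P_ICAB] * pcab * 4.0 * vffrt * (cai * ex2 - 0.341 * cao) / (ex2 - 1.0)
    gpca = 0.0005
    ipca = P[P_IPCA] * gpca * cai / (0.0005 + cai)

    # --- fluxes ---
    jdiffna = (nass - nai) / 2.0
    jdiffk = (kss - ki) / 2.0
    jdiff = (cass - cai) / 0.2

    bt = 4.75
    a_rel = 0.5 * bt
    jrel_inf = a_rel * (-ical) / (1.0 + (1.5 / cajsr) ** 8)
    tau_rel = bt / (1.0 + 0.0123 / cajsr)
    if tau_rel < 0.001:
        tau_rel = 0.001
    btp = 1.25 * bt
    a_relp = 0.5 * btp
    jrel_infp = a_relp * (-ical) / (1.0 + (1.5 / cajsr) ** 8)
    tau_relp = btp / (1.0 + 0.0123 / cajsr)
    if tau_relp < 0.001:
        tau_relp = 0.001
    inf[IJRELNP], tau[IJRELNP] = jrel_inf, tau_rel
    inf[IJRELP], tau[IJRELP] = jrel_infp, tau_relp
    jrel = (1.0 - fp) * y[IJRELNP] + fp * y[IJRELP]

    jupnp = 0.004375 * cai / (cai + 0.00092)
    jupp = 2.75 * 0.004375 * cai / (cai + 0.00092 - 0.00017)
    upscale = 1.3  # epicardial scaling
    jleak = 0.0039375 * cansr / 15.0
    jup = upscale * ((1.0 - fp) * jupnp + fp * jupp) - jleak
    jtr = (cansr - cajsr) / 100.0

    # --- ionic concentration derivatives ---
    cmdnmax = 0.05 * 1.3  # epicardial scaling
    kmcmdn = 0.00238
    trpnmax = 0.07
    kmtrpn = 0.0005
    bsrmax = 0.047
    kmbsr = 0.00087
    bslmax = 1.124
    kmbsl = 0.0087
    csqnmax = 10.0
    kmcsqn = 0.8

    dy[INAI] = -(ina + inal + 3.0 * inaca_i + 3.0 * inak + inab) * _ACAP / (_F * _VMYO) + jdiffna * _VSS / _VMYO
    dy[INASS] = -(icana + 3.0 * inaca_ss) * _ACAP / (_F * _VSS) - jdiffna
    dy[IKI] = -(ito + ikr + iks + ik1 + ikb + istim - 2.0 * inak) * _ACAP / (_F * _VMYO) + jdiffk * _VSS / _VMYO
    dy[IKSS] = -icak * _ACAP / (_F * _VSS) - jdiffk
    bcai = 1.0 / (1.0 + cmdnmax * kmcmdn / (kmcmdn + cai) ** 2 + trpnmax * kmtrpn / (kmtrpn + cai) ** 2)
    dy[ICAI] = bcai * (
        -(ipca + icab - 2.0 * inaca_i) * _ACAP / (2.0 * _F * _VMYO) - jup * _VNSR / _VMYO + jdiff * _VSS / _VMYO
    )
    bcass = 1.0 / (1.0 + bsrmax * kmbsr / (kmbsr + cass) ** 2 + bslmax * kmbsl / (kmbsl + cass) ** 2)
    dy[ICASS] = bcass * (-(ical - 2.0 * inaca_ss) * _ACAP / (2.0 * _F * _VSS) + jrel * _VJSR / _VSS - jdiff)
    dy[ICANSR] = jup - jtr * _VJSR / _VNSR
    bcajsr = 1.0 / (1.0 + csqnmax * kmcsqn / (kmcsqn + cajsr) ** 2)
    dy[ICAJSR] = bcajsr * (jtr - jrel)

    dy[IV] = -(
        ina + inal + ito + ical + icana + icak + ikr + iks + ik1
        + inaca_i + inaca_ss + inak + inab + ikb + ipca + icab + istim
    )

    # derivatives of the relaxation states (for generic ODE solvers)
    for i in range(IM, ICAMKT):
        dy[i] = (inf[i] - y[i]) / tau[i]

    cur[C_INA] = ina
    cur[C_INAL] = inal
    cur[C_ITO] = ito
    cur[C_ICAL] = ical
    cur[C_ICANA] = icana
    cur[C_ICAK] = icak
    cur[C_IKR] = ikr
    cur[C_IKS] = iks
    cur[C_IK1] = ik1
    cur[C_INACA_I] = inaca_i
    cur[C_INACA_SS] = inaca_ss
    cur[C_INAK] = inak
    cur[C_INAB] = inab
    cur[C_IKB] = ikb
    cur[C_IPCA] = ipca
    cur[C_ICAB] = icab


@njit(cache=True)
def rhs(t, y, P, istim):
    """Plain derivative evaluation (used by scipy solvers and API wrappers)."""
    dy = np.empty(NY)
    inf = np.empty(NY)
    tau = np.empty(NY)
    cur = np.empty(NCUR)
    rates(y, P, istim, dy, inf, tau, cur)
    return dy


@njit(cache=True)
def pace(
    y,
    P,
    cl,
    n_prepace,
    n_record,
    min_prepace,
    ss_tol,
    dt_out,
    dv_target,
    dt_min,
    dt_max_ap,
    dt_max_dia,
    apd_level,
    record_currents,
):
    """Pace the model for ``n_prepace`` (+ optional early stop) then
    ``n_record`` beats at cycle length ``cl``.

    Returns per-beat biomarkers for every simulated beat and uniformly
    resampled traces (membrane potential, [Ca2+]i, optionally all currents)
    for the recorded beats. ``y`` is advanced in place.

    Early stop: prepacing ends once |dAPD90| between consecutive beats stays
    below ``ss_tol`` for 10 beats (and at least ``min_prepace`` beats ran);
    ``ss_tol <= 0`` disables it.
    """
    nmax = n_prepace + n_record
    apd = np.full(nmax, np.nan)
    rmp = np.full(nmax, np.nan)
    vpeak = np.full(nmax, np.nan)
    cat_min = np.full(nmax, np.nan)
    cat_max = np.full(nmax, np.nan)
    dvdtmax = np.full(nmax, np.nan)

    n_out = int(cl / dt_out) + 1
    rec_v = np.empty((n_record, n_out))
    rec_cai = np.empty((n_record, n_out))
    if record_currents:
        rec_cur = np.empty((n_record, n_out, NCUR))
    else:
        rec_cur = np.empty((0, n_out, NCUR))

    dy = np.empty(NY)
    inf = np.empty(NY)
    tau = np.empty(NY)
    cur = np.empty(NCUR)

    stim_amp = P[P_STIMAMP]
    stim_dur = P[P_STIMDUR]

    prepace_done = n_prepace == 0
    consec = 0
    prepace_count = n_prepace
    rec_i = 0
    b = 0
    while rec_i < n_record and b < nmax:
        record_this = prepace_done
        rmp_b = y[IV]
        v_prev = y[IV]
        cai_min = y[ICAI]
        cai_max = y[ICAI]
        v_pk = y[IV]
        t_pk = 0.0
        dvdt_mx = -1.0e30
        t_up = 0.0
        apd_b = np.nan
        crossed = False
        out_k = 0
        t = 0.0
        dt = dt_min
        dvdt = 0.0
        while t < cl - 1e-9:
            # step-size selection from last dV/dt, phase-capped
            adt = dv_target / (np.abs(dvdt) + 1e-12)
            if adt < dt_min:
                adt = dt_min
            cap = dt_max_ap
            if y[IV] < -70.0 and np.abs(dvdt) < 0.1 and t > 50.0:
                cap = dt_max_dia
            if t < 20.0:
                cap = 0.05 if cap > 0.05 else cap
            if adt > cap:
                adt = cap
            dt = adt
            # do not step across the stimulus edge or beat end
            if t < stim_dur and t + dt > stim_dur:
                dt = stim_dur - t
            if t + dt > cl:
                dt = cl - t
            istim = stim_amp if t < stim_dur - 1e-12 else 0.0

            rates(y, P, istim, dy, inf, tau, cur)
            if not np.isfinite(dy[IV]):
                # signal solver failure with NaN biomarkers
                apd[b] = np.nan
                return apd, rmp, vpeak, cat_min, cat_max, dvdtmax, rec_v, rec_cai, rec_cur, b, prepace_count, -1
            t_new = t + dt
            v_old = y[IV]
            cai_old = y[ICAI]
            # forward Euler for voltage, concentrations, CaMK
            y[IV] += dt * dy[IV]
            for i in range(INAI, IM):
                y[i] += dt * dy[i]
            y[ICAMKT] += dt * dy[ICAMKT]
            # exact exponential update for relaxation states
            for i in range(IM, ICAMKT):
                e = np.exp(-dt / tau[i])
                y[i] = inf[i] + (y[i] - inf[i]) * e

            dvdt = (y[IV] - v_old) / dt
            if dvdt > dvdt_mx:
                dvdt_mx = dvdt
                t_up = t_new
            if y[IV] > v_pk:
                v_pk = y[IV]
                t_pk = t_new
            if y[ICAI] < cai_min:
                cai_min = y[ICAI]
            if y[ICAI] > cai_max:
                cai_max = y[ICAI]
            # APD: first downward crossing of the repolarization level after the peak
            if not crossed and t_new > t_pk and t_new > t_up:
                v_level = v_pk - apd_level / 100.0 * (v_pk - rmp_b)
                if v_old >= v_level and y[IV] < v_level:
                    frac = (v_old - v_level) / (v_old - y[IV])
                    apd_b = (t + frac * dt) - t_up
                    crossed = True
            # resample onto the uniform output grid
            if record_this:
                while out_k < n_out and out_k * dt_out <= t_new + 1e-9:
                    tg = out_k * dt_out
                    w = (tg - t) / dt if dt > 0 else 0.0
                    if w < 0.0:
                        w = 0.0
                    if w > 1.0:
                        w = 1.0
                    rec_v[rec_i, out_k] = v_old + w * (y[IV] - v_old)
                    rec_cai[rec_i, out_k] = cai_old + w * (y[ICAI] - cai_old)
                    if record_currents:
                        for ci in range(NCUR):
                            rec_cur[rec_i, out_k, ci] = cur[ci]
                    out_k += 1
            t = t_new

        apd[b] = apd_b
        rmp[b] = rmp_b
        vpeak[b] = v_pk
        cat_min[b] = cai_min
        cat_max[b] = cai_max
        dvdtmax[b] = dvdt_mx
        if record_this:
            rec_i += 1
        else:
            if ss_tol > 0.0 and b > 0:
                d = np.abs(apd[b] - apd[b - 1])
                if np.isfinite(d) and d < ss_tol:
                    consec += 1
                else:
                    consec = 0
            if (ss_tol > 0.0 and consec >= 10 and b + 1 >= min_prepace) or b + 1 >= n_prepace:
                prepace_done = True
                prepace_count = b + 1
        b += 1

    return apd, rmp, vpeak, cat_min, cat_max, dvdtmax, rec_v, rec_cai, rec_cur, b, prepace_count, 0
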