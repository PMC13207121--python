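# Default pathway gene panels for hypermobile Ehlers-Danlos syndrome (hEDS)
# prioritization. Each pathway maps to the gene symbols this package ships
# by default; the file is user-extensible and a gene may appear in several
# pathways. `family_shared` marks the pathways harboring the three
# family-derived causative genes (HA-ECM axis, ECM remodeling, cell-matrix
# adhesion).
pathways:
  HA-ECM axis:
    family_shared: true
    genes:
      - CD44
      - ITIH1
      - ITIH2
      - ITIH3
      - ITIH4
      - ITIH5
      - ITIH6
      - HMMR
      - STAB2
  ECM remodeling:
    family_shared: true
    genes:
      - ADAM7
      - ADAM21
      - ADAM32
      - ADAM33
      - ADAMTS7P1
      - MMP7
      - MMP8
      - MMP24
      - TIMP1
      - RLN1
      - CAPN9
      - TGM6
      - THSD4
  ECM structural:
    genes:
      - COL28A1
      - HSPG2
      - HMCN1
      - EMILIN2
      - VWA5B1
      - VWA3B
      - PKHD1L1
      - USH2A
      - TECTA
  Cell-matrix adhesion and mechanotransduction:
    family_shared: true
    genes:
      - ITGA4
      - PIEZO1
      - EFNB2
      - CLDN1
      - CLDN2
      - PTPRM
      - PTPRQ
      - CDH26
      - SEMA4A
      - NFASC
      - ASAP1
      - ATRN
      - PLA2R1
      - PCDHGA11
      - PCDHGB4
      - PCDHB10
      - MEGF10
  Cytoskeleton regulation:
    genes:
      - SPTA1
      - SPTBN4
      - FGD4
      - SSH2
      - SHANK2
      - PDLIM5
      - XIRP2
      - PLS1
      - WIPF3
      - MYL6
      - TUBA3C
      - GFAP
      - CDC42BPB
      - COBLL1
      - ANK2
  TGF-beta/BMP/Wnt signaling:
    genes:
      - SOX9
      - KCP
      - RSPO4
      - FGFBP1
      - AREG
      - OSMR
      - PDGFRL
      - IRS1
  Collagen processing and ER quality control:
    genes:
      - SEC23A
      - POMT1
      - DNAJB9
      - EDEM2
      - COL11A2
      - POMGNT1
      - SLC35D1
  Complement/immune/mast cell:
    genes:
      - GSDMA
      - GSDME
      - FCRL4
      - IL1A
      - IL36B
      - SIGIRR
      - TICAM2
      - TCIRG1
      - FCGBP
  Vascular/autonomic/ion channel:
    genes:
      - ANGPT2
      - SCN3A
      - SCN5A
      - SCN9A
      - KCNH6
      - KCNQ4
      - TRPV6
      - CHRNA3
      - ITPR2
      - GLRB
      - NOSTRIN
  Muscle/cardiac/skeletal/wound healing:
    genes:
      - TTN
      - CMYA5
      - ALPL
      - SLC26A2
      - PROM1
      - MYH8
      - MYOM2
      - NEBL
      - TRDN
      - TRIM72
      - F7
      - COX7C
      - CGREF1
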