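LOCUS       NP002829                1306 aa                     UNK 01-JAN-2000
DEFINITION  Receptor-type tyrosine-protein phosphatase C (synthetic stand-in).
ACCESSION   NP_002829
VERSION     NP_002829.3
KEYWORDS    .
SOURCE      .
  ORGANISM  .
            .
FEATURES             Location/Qualifiers
     source          1..1306
                     /organism="Homo sapiens"
                     /note="synthetic stand-in sequence"
     sig_peptide     1..23
     Region          391..486
                     /region_name="Fibronectin type-III 1"
     Region          491..575
                     /region_name="Fibronectin type-III 2"
     Region          578..601
                     /region_name="Transmembrane region"
     Region          653..912
                     /region_name="PTPc 1"
                     /note="Protein tyrosine phosphatase, catalytic domain"
     Region          944..1236
                     /region_name="PTPc 2"
     Site            828
                     /site_type="active"
     Site            965
                     /site_type="phosphorylation"
                     /note="Phosphoserine"
     Site            223
                     /site_type="glycosylation"
                     /note="N-linked (GlcNAc...) asparagine"
     Site            373
                     /site_type="glycosylation"
                     /note="N-linked (GlcNAc...) asparagine"
ORIGIN
        1 mlispvprek gvgimiavrm gywltdctsd fhqnfmacvp mrymkgyprm hnykcigtqv
       61 peeltfywlp kvsyvaislc lhychgamym vlsycamhfm awkhdyapns dkkrasqhrn
      121 emimkfncvk vritdftndp rqwkikpdcm kapmtdwgrv lvganreymn fpwwwnkcdl
      181 wisrvyymqy ndqaeqvinc gmvyqqdvvg haasqfnpiw qlvqfefrnm gmeqkslcww
      241 iyvfwinemh eqkvfklccm memvsymtef kismwwhtcm rlyygtfymt ieidglghwl
      301 fstkfaealk vqynkwktgl hnlqsardnl tepacgpiwp padnaaypng rfcccyfnee
      361 wrvkigwalm iikysivprs ymrcdgecmv ydgcfwiqyn nwprgklppq wvhqylvgnv
      421 gnhvpendty mvvcsstytk snqdvfmfra qemeymclwr lprghfafhe hciydgeicd
      481 gdvhttscfg vgwvvliadl whimqilidm yfamvmsdgg tlnqcirqcm rmhshyghkq
      541 tmnmmipaln rgqyrywaya stgssecmpv veyrysdhlf dpaytpapgc knghnvkvdf
      601 rniksnqphe iwkwhsmwlc ifkncaadsg hggwcwkgev tckapknlfy stwvariiai
      661 ykliccaecm gdyinvmqkh ictrypwhrp cehkakymcg mdemwdnvin qlgrvlctnr
      721 vplitdnkgt nsavmnfncw knlkwnnwgr lifkctvavr dvvhdnswwn slrnlhsgwm
      781 dqtddemfwm rvgqwhrqhh gvmqygcyhr iwamrwpvtr hyafslidtr nlgdfeimgv
      841 ttwrpgsevg sqqkadfymg rpwalrsfpq tshsgisdpv layvaklfmk rscmardnyp
      901 hmqpwlrsme ehknycfmwn flydregdii qfegkniath hgallgwtwp fivynwcfwd
      961 sfmfslesql rdlrfmmwpe yhpwdmwcgg ckgmdmclff ayqalnhnst hpnlklfyqy
     1021 wfnkapeyki isqwvphqwl viseapplmp hlhwhnrprr kqsfwcynip tllcivnnnw
     1081 ksafgallwe imrsfwlimq mdqkdyvrrh ntwdeyfdvy acqqyvmqkk lhfyvrevke
     1141 mctgvmwcfi cqtcmlayrr dpsivhmpsq iwsnihseyd kcneylmesd gngemnavdl
     1201 mwvmlcknfq clvgsvknrr tcykcyrrtk fgersncgnq hengsnakms lknlchcgsf
     1261 dlfcdrqlip rqrhaaktin wtcgfiddcp kpnmvahaky ispqtg
//
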