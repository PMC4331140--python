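code,concept,record_kind,class
AST01,asthma_dx,event,
AST02,asthma_dx,event,
AST03,asthma_dx,event,
CPD01,copd_dx,event,
CPD02,copd_dx,event,
CPD03,copd_dx,event,
CYF01,cystic_fibrosis_dx,event,
CYF02,cystic_fibrosis_dx,event,
LCA01,lung_cancer_dx,event,
LCA02,lung_cancer_dx,event,
BRX01,bronchiectasis_dx,event,
BRX02,bronchiectasis_dx,event,
FIB01,fibrotic_lung_disease_dx,event,
FIB02,fibrotic_lung_disease_dx,event,
RXS01,saba,prescription,SABA
RXS02,saba,prescription,SABA
RXS03,saba,prescription,SABA
RXS04,saba,prescription,SABA
RXL01,laba,prescription,LABA
RXL02,laba,prescription,LABA
RXL03,laba,prescription,LABA
RXM01,lama,prescription,LAMA
RXM02,lama,prescription,LAMA
RXM03,lama,prescription,LAMA
RXI01,ics,prescription,ICS
RXI02,ics,prescription,ICS
RXI03,ics,prescription,ICS
RXI04,ics,prescription,ICS
RXC01,ics_laba,prescription,ICS_LABA
RXC02,ics_laba,prescription,ICS_LABA
RXC03,ics_laba,prescription,ICS_LABA
RXT01,ltra,prescription,LTRA
RXT02,ltra,prescription,LTRA
RXO01,ocs,prescription,OCS
RXO02,ocs,prescription,OCS
RXO03,ocs,prescription,OCS
RXA01,antibiotic,prescription,ABX
RXA02,antibiotic,prescription,ABX
RXA03,antibiotic,prescription,ABX
RXA04,antibiotic,prescription,ABX
RXA05,antibiotic,prescription,ABX
GPV01,gp_visit,event,
GPV02,gp_visit,event,
GPV03,gp_visit,event,
ADR01,resp_admission,event,
ADR02,resp_admission,event,
ADR03,resp_admission,event,
ADN01,nonresp_admission,event,
ADN02,nonresp_admission,event,
ADN03,nonresp_admission,event,
MFE01,fev1,event,
MFP01,fev1_pct_pred,event,
MPF01,pef,event,
MSM01,smoking_status,event,
MBM01,bmi,event,
XDE01,death,event,
XDR01,deregistration,event,
CVM01,mi,event,
CVM02,mi,event,
CVH01,hypertension,event,
CVH02,hypertension,event,
CVS01,stroke,event,
CVS02,stroke,event,
CVF01,heart_failure,event,
CVF02,heart_failure,event,
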