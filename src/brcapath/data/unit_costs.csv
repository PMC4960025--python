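label,cost_gbp,unit,category,staff_time,source
oncology_referral,168.00,per_item,referral,false,NHS reference costs 2012-13 (oncology outpatient)
referral_received,5.07,per_item,administration,true,primary data collection
referral_triaged,1.17,per_item,administration,true,primary data collection
request_documents,8.82,per_item,administration,true,primary data collection
clinical_review,21.85,per_item,administration,true,primary data collection
appointment_arranged,3.49,per_item,administration,true,primary data collection
clinic_preparation,2.74,per_item,administration,true,primary data collection
clinic_appointment,104.80,per_item,clinic,true,primary data collection
post_appointment_letter,11.18,per_item,clinic,true,primary data collection
post_appointment_admin,5.17,per_item,clinic,true,primary data collection
phlebotomy,3.00,per_item,sample,true,primary data collection
full_gene_test,540.00,per_item,test,false,laboratory charge 2013 (ex VAT)
mammography,45.50,per_item,management,false,published screening cost estimate
mri,145.88,per_item,management,false,NHS reference costs 2013
mastectomy,6784.00,per_item,management,false,NHS reference costs 2013
salpingo_oophorectomy,3355.43,per_item,management,false,NHS reference costs 2013
band3_administrative_assistant,17.19,per_hour,staff_rate,true,Agenda for Change 2013 (London)
band5_medical_secretary,23.48,per_hour,staff_rate,true,Agenda for Change 2013 (London)
band6_administrative_lead,28.74,per_hour,staff_rate,true,Agenda for Change 2013 (London)
band8_genetic_counsellor,55.54,per_hour,staff_rate,true,Agenda for Change 2013 (London)
registrar,61.46,per_hour,staff_rate,true,PSSRU 2013 (London)
consultant,139.73,per_hour,staff_rate,true,PSSRU 2013 (London)
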