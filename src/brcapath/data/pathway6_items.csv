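group,label,cost_gbp
oncology_referral,oncology_referral,168.00
appointment_administration,referral_received,5.07
appointment_administration,referral_triaged,1.17
appointment_administration,request_documents,8.82
appointment_administration,clinical_review,21.85
appointment_administration,appointment_arranged,3.49
appointment_administration,clinic_preparation,2.74
clinic_related_activity,clinic_appointment,104.80
clinic_related_activity,post_appointment_letter,11.18
clinic_related_activity,post_appointment_admin,5.17
blood_sample,phlebotomy,3.00
blood_sample,full_gene_test,540.00
follow_up_administration,appointment_arranged,3.49
follow_up_administration,clinic_preparation,2.74
follow_up_clinic_activity,clinic_appointment,104.80
follow_up_clinic_activity,post_appointment_letter,11.18
follow_up_clinic_activity,post_appointment_admin,5.17
higher_risk_surveillance,surveillance_higher,628.30
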