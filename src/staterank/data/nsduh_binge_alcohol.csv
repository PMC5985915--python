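state,prevalence_pct,se_pct,published_rank
Alabama,9.7,1.1,22
Alaska,7.0,1.1,47
Arizona,8.1,1.0,40
Arkansas,10.1,1.4,19
California,9.5,0.5,25
Colorado,10.0,1.2,20
Connecticut,9.8,1.4,21
Delaware,8.0,1.2,41
District of Columbia,8.4,1.4,37
Florida,8.6,0.5,35
Georgia,8.8,1.0,33
Hawaii,10.6,1.2,15
Idaho,9.6,1.2,23
Illinois,8.6,0.6,35
Indiana,8.4,1.1,37
Iowa,9.7,1.1,22
Kansas,10.4,1.4,16
Kentucky,7.3,1.0,46
Louisiana,11.0,1.4,12
Maine,8.7,1.1,34
Maryland,10.3,1.2,17
Massachusetts,12.3,1.2,5
Michigan,9.8,0.7,21
Minnesota,7.5,0.9,45
Mississippi,8.5,1.2,36
Missouri,10.2,1.4,18
Montana,11.5,1.4,9
Nebraska,8.7,1.2,34
Nevada,9.0,1.5,30
New Hampshire,11.8,1.2,7
New Jersey,14.3,1.4,1
New Mexico,9.5,1.4,25
New York,11.7,0.8,8
North Carolina,8.6,1.1,35
North Dakota,8.6,1.2,35
Ohio,9.3,0.6,27
Oklahoma,8.3,1.1,38
Oregon,12.1,1.3,6
Pennsylvania,10.3,0.7,17
Rhode Island,9.1,1.3,29
South Carolina,8.3,1.2,38
South Dakota,11.4,1.5,9
Tennessee,7.0,0.9,47
Texas,8.6,0.6,35
Utah,5.9,1.1,50
Vermont,13.6,1.4,2
Virginia,8.1,0.9,40
Washington,9.5,1.2,25
West Virginia,11.4,1.2,9
Wisconsin,9.2,1.2,28
Wyoming,11.0,1.3,12
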